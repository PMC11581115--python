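"""Aligned (5-s LFP window -> scalar label) datasets and visit splitting.

Each label time ``t`` pairs the normalized weight shift over (t−2 s, t]
with the LFP over (t−5 s, t] — 1055 samples per channel at 211 Hz, the
window end snapped to the LFP sample nearest ``t`` (the 0.1-s label stride
is 21.1 LFP samples, so the snap introduces at most ~2.4 ms jitter).
Windows without a full 5-s history are dropped.

Visits are assigned to roles strictly chronologically: third most recent
trains, second most recent validates, most recent tests — emulating
prospective deployment where the model only ever sees past data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .gait import WeightShiftSeries
from .preprocess import ForcePlatePair, LfpRecording

WINDOW_S = 5.0


@dataclass
class SessionRecord:
    """One preprocessed visit: LFP, forces and normalized labels."""

    lfp: LfpRecording
    force: ForcePlatePair
    labels: WeightShiftSeries
    visit_index: int
    contacts_id: str = "contacts-0"


@dataclass
class WindowedDataset:
    """Model-ready windows: inputs (N, 2, 1055), labels in [0,1]."""

    inputs: np.ndarray
    labels: np.ndarray
    label_times_s: np.ndarray
    role: str
    visit_index: int

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def subsample(self, step: int) -> "WindowedDataset":
        """Every ``step``-th window (coarser stride for desk-scale runs)."""
        return WindowedDataset(self.inputs[::step], self.labels[::step],
                               self.label_times_s[::step], self.role,
                               self.visit_index)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.asarray(self.inputs, dtype=np.float32).tofile(d / "inputs.bin")
        with open(d / "shape.json", "w") as fh:
            json.dump({"shape": list(self.inputs.shape),
                       "dtype": "float32", "role": self.role,
                       "visit_index": self.visit_index}, fh)
        np.savetxt(d / "labels.csv",
                   np.column_stack([self.label_times_s, self.labels]),
                   delimiter=",", header="time_s,label", comments="")

    @classmethod
    def load(cls, directory: str | Path) -> "WindowedDataset":
        d = Path(directory)
        with open(d / "shape.json") as fh:
            meta = json.load(fh)
        inputs = np.fromfile(d / "inputs.bin", dtype=np.float32).reshape(
            meta["shape"])
        table = np.loadtxt(d / "labels.csv", delimiter=",", skiprows=1,
                           ndmin=2)
        return cls(inputs=inputs, labels=table[:, 1],
                   label_times_s=table[:, 0], role=meta["role"],
                   visit_index=meta["visit_index"])


def build_windows(session: SessionRecord, role: str = "unassigned",
                  window_s: float = WINDOW_S) -> WindowedDataset:
    """Pair every label with its trailing 5-s LFP window.

    Requires preprocessed LFP (211 Hz) and labels on the 0.1-s grid; label
    times must lie inside the LFP's time range.
    """
    lfp = session.lfp
    labels = session.labels
    if labels.normalized is None:
        raise ValueError("labels must be normalized across visits first")
    n_win = int(round(window_s * lfp.fs_hz))
    t_total = lfp.n_samples
    end_idx = np.rint(labels.times_s * lfp.fs_hz).astype(int)
    if np.any(end_idx > t_total - 1):
        raise ValueError("label times extend beyond the LFP recording")
    keep = end_idx >= n_win - 1
    if not np.any(keep):
        raise ValueError(
            f"session too short: no label has a full {window_s}-s LFP "
            "history")
    end_idx = end_idx[keep]
    windows = sliding_window_view(lfp.samples, n_win, axis=1)
    inputs = np.ascontiguousarray(
        windows[:, end_idx - (n_win - 1)].transpose(1, 0, 2),
        dtype=np.float32)
    return WindowedDataset(
        inputs=inputs,
        labels=np.asarray(labels.normalized)[keep].astype(float),
        label_times_s=labels.times_s[keep],
        role=role, visit_index=session.visit_index)


def chronological_split(sessions: list[SessionRecord],
                        window_s: float = WINDOW_S
                        ) -> tuple[WindowedDataset, WindowedDataset,
                                   WindowedDataset]:
    """Assign exactly three visits to train/validation/test by recency."""
    if len(sessions) < 3:
        raise ValueError(
            f"need 3 visits for the chronological split, got "
            f"{len(sessions)}")
    if len(sessions) > 3:
        raise ValueError(
            f"expected exactly 3 eligible visits, got {len(sessions)}; "
            "select the three most recent consistent-contact visits first")
    ordered = sorted(sessions, key=lambda s: s.visit_index)
    ref = ordered[0].contacts_id
    for s in ordered[1:]:
        if s.contacts_id != ref:
            raise ValueError(
                f"recording contacts changed on visit {s.visit_index} "
                f"({s.contacts_id!r} != {ref!r}); visits are not "
                "comparable")
    roles = ("train", "validation", "test")
    return tuple(build_windows(s, role=r, window_s=window_s)
                 for s, r in zip(ordered, roles))
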