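"""On-disk session format: two CSV files plus a JSON sidecar per visit.

A visit directory contains ``lfp.csv`` (time_s, left_stn, right_stn),
``force.csv`` (time_s, left_n, right_n) and ``meta.json`` with sampling
rates, units, body weight, visit index, contacts id and — for synthetic
sessions — an echo of the generator parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ForcePlatePair, LfpRecording
from .synth import RawSession, SynthParams


def save_session(directory: str | Path, session: RawSession) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lfp, force = session.lfp, session.force
    pd.DataFrame({
        "time_s": lfp.times_s,
        "left_stn": lfp.samples[0],
        "right_stn": lfp.samples[1],
    }).to_csv(d / "lfp.csv", index=False, float_format="%.6g")
    pd.DataFrame({
        "time_s": force.times_s,
        "left_n": force.samples[0],
        "right_n": force.samples[1],
    }).to_csv(d / "force.csv", index=False, float_format="%.6g")
    meta = {
        "lfp_fs_hz": lfp.fs_hz,
        "lfp_band_hz": list(lfp.band_hz) if isinstance(lfp.band_hz, tuple)
        else lfp.band_hz,
        "lfp_units": "a.u.",
        "force_fs_hz": force.fs_hz,
        "force_units": "N",
        "body_weight_n": force.body_weight_n,
        "visit_index": session.visit_index,
        "contacts_id": session.contacts_id,
        "lfp_provenance": lfp.provenance,
        "force_provenance": force.provenance,
    }
    if session.params is not None:
        meta["synth_params"] = session.params.to_dict()
    with open(d / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return d


def load_session(directory: str | Path) -> RawSession:
    d = Path(directory)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    lfp_df = pd.read_csv(d / "lfp.csv")
    force_df = pd.read_csv(d / "force.csv")
    band = meta.get("lfp_band_hz", "raw")
    lfp = LfpRecording(
        samples=np.stack([lfp_df["left_stn"], lfp_df["right_stn"]]),
        fs_hz=meta["lfp_fs_hz"],
        band_hz=tuple(band) if isinstance(band, list) else band,
        provenance=list(meta.get("lfp_provenance", [])))
    force = ForcePlatePair(
        samples=np.stack([force_df["left_n"], force_df["right_n"]]),
        fs_hz=meta["force_fs_hz"],
        body_weight_n=meta["body_weight_n"],
        provenance=list(meta.get("force_provenance", [])))
    params = (SynthParams.from_dict(meta["synth_params"])
              if "synth_params" in meta else None)
    return RawSession(lfp=lfp, force=force,
                      visit_index=meta["visit_index"],
                      contacts_id=meta["contacts_id"], truth=None,
                      params=params)


def save_participant(directory: str | Path,
                     sessions: list[RawSession]) -> list[Path]:
    root = Path(directory)
    return [save_session(root / f"visit{s.visit_index}", s)
            for s in sessions]


def load_participant(directory: str | Path) -> list[RawSession]:
    root = Path(directory)
    visit_dirs = sorted(p for p in root.iterdir()
                        if p.is_dir() and (p / "meta.json").exists())
    if not visit_dirs:
        raise FileNotFoundError(f"no visit directories under {root}")
    sessions = [load_session(p) for p in visit_dirs]
    return sorted(sessions, key=lambda s: s.visit_index)
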