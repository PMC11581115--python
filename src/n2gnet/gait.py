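"""Weight-shift gait labels from dual force-plate traces.

The gait-performance label is built in four steps:

1. divide both force channels by the participant's body weight (measured
   while motionless), so labels are robust to weight changes across visits;
2. merge the two unit-normalized channels into one stance value per sample
   by taking the higher of the two and mirroring left-plate samples about
   0.5 — high values mean weight on the right plate, low values weight on
   the left, and lower-force (including foot-off) samples are disregarded;
3. quantify the change of the merged trace over a sliding 2-s window —
   implemented as the window's total variation (sum of absolute successive
   differences), which is zero for a motionless stance and grows with both
   the amplitude and the number of weight shifts;
4. rescale per participant so the maximum 2-s shift across the visits maps
   to 1 and a completely motionless state to 0.

The total-variation definition in step 3 is this package's reconstruction
of the windowed "change in force" statistic; it is the one formula here
that is a design choice rather than a published definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ForcePlatePair


@dataclass
class MergedStance:
    """Per-sample merged/mirrored stance in [0,1] at the force rate."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WeightShiftSeries:
    """Windowed weight-shift magnitudes and their normalized labels."""

    times_s: np.ndarray
    raw_shift: np.ndarray
    normalized: np.ndarray | None = None
    window_s: float = 2.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.raw_shift = np.asarray(self.raw_shift, dtype=float)


def normalize_by_weight(rec: ForcePlatePair) -> ForcePlatePair:
    """Rescale both channels to body-weight units (quiet standing ~0.5)."""
    if rec.body_weight_n <= 0:
        raise ValueError("body weight must be positive")
    return ForcePlatePair(
        samples=rec.samples / rec.body_weight_n, fs_hz=rec.fs_hz,
        body_weight_n=1.0,
        provenance=rec.provenance + ["normalize_by_weight"])


def merge_and_mirror(pair: ForcePlatePair) -> MergedStance:
    """Collapse the unit-normalized pair to a single stance value.

    Per sample the higher channel wins: if the right plate reads more, its
    value is kept; otherwise the left-plate value is mirrored about 0.5
    (1 − left). The result is clipped to [0,1].
    """
    left, right = pair.samples
    if left.shape != right.shape:
        raise ValueError("force channels must have equal length")
    merged = np.where(right >= left, right, 1.0 - left)
    return MergedStance(values=np.clip(merged, 0.0, 1.0), fs_hz=pair.fs_hz)


def windowed_shift(m: MergedStance, window_s: float = 2.0,
                   stride_s: float = 0.1) -> WeightShiftSeries:
    """Total variation of the merged stance over a sliding 2-s window.

    Labels are emitted every ``stride_s`` on the force-sample grid, from
    ``window_s`` to the end of the recording. A constant stretch yields 0;
    one full 0.5 Hz sinusoidal cycle of amplitude A yields ~4A.
    """
    values = m.values
    n_win = int(round(window_s * m.fs_hz))
    stride = int(round(stride_s * m.fs_hz))
    if values.size <= n_win:
        raise ValueError(
            f"recording ({values.size} samples) shorter than the "
            f"{window_s}-s window")
    increments = np.abs(np.diff(values))
    csum = np.concatenate([[0.0], np.cumsum(increments)])
    idx = np.arange(n_win, values.size, stride)
    raw = csum[idx] - csum[idx - n_win]
    return WeightShiftSeries(times_s=idx / m.fs_hz, raw_shift=raw,
                             window_s=window_s)


def normalize_across_visits(series_per_visit: list[WeightShiftSeries]
                            ) -> tuple[list[WeightShiftSeries], float]:
    """Scale all visits by the participant-level maximum raw shift.

    Returns the rescaled series and the scaling constant, which callers
    must reuse for any later visit of the same participant (test labels are
    normalized with the constant fitted on the provided visits).
    """
    if not series_per_visit:
        raise ValueError("need at least one visit")
    scale = max(float(s.raw_shift.max()) for s in series_per_visit)
    if scale <= 0:
        raise ValueError("no weight shift observed in any visit; cannot "
                         "normalize an entirely motionless participant")
    out = [replace(s, normalized=s.raw_shift / scale)
           for s in series_per_visit]
    return out, scale


def labels_from_force(rec: ForcePlatePair, window_s: float = 2.0,
                      stride_s: float = 0.1) -> WeightShiftSeries:
    """Convenience: weight-normalize, merge/mirror and window one visit."""
    return windowed_shift(merge_and_mirror(normalize_by_weight(rec)),
                          window_s=window_s, stride_s=stride_s)
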