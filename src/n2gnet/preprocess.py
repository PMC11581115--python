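"""Filtering and resampling of raw LFP and force-plate recordings.

The pipeline's canonical rates are 211 Hz for LFP (decimated from the
422 Hz acquisition rate) and 100 Hz for force plates (Bertec systems record
at 1000 Hz and are decimated; Neurocom records at 100 Hz natively). LFP is
band-passed 8–100 Hz to retain the movement-relevant spectrum; force traces
are low-passed at 2 Hz to suppress jerky non-gait transients.

All filters are zero-phase (forward-backward order-4 Butterworth), because
the 5-s-window / 2-s-label temporal alignment downstream must not be skewed
by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class LfpRecording:
    """Two-channel (left/right STN) uniformly sampled LFP series.

    ``band_hz`` records the applied pass-band, or ``"raw"`` before
    filtering; ``provenance`` is the ordered list of applied transforms.
    """

    samples: np.ndarray            # (2, T)
    fs_hz: float
    band_hz: tuple | str = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != 2:
            raise ValueError("LfpRecording expects exactly 2 channels")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class ForcePlatePair:
    """Left/right vertical ground-reaction force in newtons."""

    samples: np.ndarray            # (2, T)
    fs_hz: float
    body_weight_n: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != 2:
            raise ValueError("ForcePlatePair expects exactly 2 channels")
        if self.body_weight_n <= 0:
            raise ValueError("body weight must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {what}; refusing to filter")


def bandpass_lfp(rec: LfpRecording, low_hz: float = 8.0,
                 high_hz: float = 100.0) -> LfpRecording:
    """Zero-phase order-4 Butterworth band-pass of both LFP channels."""
    nyq = rec.fs_hz / 2.0
    if low_hz >= high_hz:
        raise ValueError("low cutoff must be below high cutoff")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    if rec.fs_hz <= 2.0 * high_hz:
        raise ValueError("sampling rate must exceed twice the high cutoff")
    _check_finite(rec.samples, "LFP samples")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1, padtype="even")
    return LfpRecording(
        samples=filtered, fs_hz=rec.fs_hz, band_hz=(low_hz, high_hz),
        provenance=rec.provenance + [f"bandpass({low_hz},{high_hz})"])


def lowpass_force(rec: ForcePlatePair, cutoff_hz: float = 2.0
                  ) -> ForcePlatePair:
    """Zero-phase order-4 Butterworth low-pass; output clipped at 0 N."""
    nyq = rec.fs_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if rec.fs_hz < 10:
        raise ValueError("force sampling rate too low to filter")
    _check_finite(rec.samples, "force samples")
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=rec.fs_hz,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1, padtype="even")
    return ForcePlatePair(
        samples=np.clip(filtered, 0.0, None), fs_hz=rec.fs_hz,
        body_weight_n=rec.body_weight_n,
        provenance=rec.provenance + [f"lowpass({cutoff_hz})"])


def downsample(series: np.ndarray, from_fs: float, to_fs: float
               ) -> np.ndarray:
    """Anti-alias filter and decimate by an integer factor.

    The length of the output is ``ceil(T * to_fs / from_fs)`` and retained
    samples keep their original timestamps (every k-th sample is kept).
    """
    if to_fs <= 0 or from_fs <= 0:
        raise ValueError("sampling rates must be positive")
    factor = from_fs / to_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {factor} is not an integer "
            f"({from_fs} -> {to_fs} Hz)")
    q = int(round(factor))
    series = np.asarray(series, dtype=float)
    _check_finite(series, "series to downsample")
    if q == 1:
        return series.copy()
    return signal.decimate(series, q, ftype="iir", zero_phase=True, axis=-1)


def downsample_lfp(rec: LfpRecording, to_fs: float = 211.0) -> LfpRecording:
    out = downsample(rec.samples, rec.fs_hz, to_fs)
    return LfpRecording(
        samples=out, fs_hz=to_fs, band_hz=rec.band_hz,
        provenance=rec.provenance + [f"downsample({rec.fs_hz}->{to_fs})"])


def downsample_force(rec: ForcePlatePair, to_fs: float = 100.0
                     ) -> ForcePlatePair:
    out = downsample(rec.samples, rec.fs_hz, to_fs)
    return ForcePlatePair(
        samples=out, fs_hz=to_fs, body_weight_n=rec.body_weight_n,
        provenance=rec.provenance + [f"downsample({rec.fs_hz}->{to_fs})"])


def preprocess_lfp(rec: LfpRecording, low_hz: float = 8.0,
                   high_hz: float = 100.0, to_fs: float = 211.0
                   ) -> LfpRecording:
    """Canonical LFP path: band-pass at the acquisition rate, then decimate."""
    return downsample_lfp(bandpass_lfp(rec, low_hz, high_hz), to_fs)


def preprocess_force(rec: ForcePlatePair, cutoff_hz: float = 2.0,
                     to_fs: float = 100.0) -> ForcePlatePair:
    """Canonical force path: decimate to 100 Hz if needed, then low-pass."""
    out = rec if rec.fs_hz == to_fs else downsample_force(rec, to_fs)
    return lowpass_force(out, cutoff_hz)
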