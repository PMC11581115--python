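"""Synthetic stepping-in-place sessions with known ground truth.

Clinical recordings of this kind are not publicly available, so this module
generates sessions that emulate the statistical structure the decoding
method assumes:

* an alternating left/right stepping waveform on two force plates
  (~100-s sessions with quiet standing before the start cue and after the
  stop cue, optional freezing episodes, and slow drift in stepping vigor);
* bilateral STN-like LFP built from a 1/f aperiodic background plus
  band-limited oscillations whose amplitude envelopes are coupled — with
  configurable gain and sign — to the instantaneous movement intensity,
  plus white measurement noise.

The default coupling is movement-related beta desynchronization: the
13–36 Hz envelope *decreases* while the subject is actively shifting
weight (sign −1). Ground truth (stance, per-band envelopes, the coupled
band) is returned alongside each session so downstream stages can be tested
for parameter recovery.

Everything is driven by ``numpy.random.Generator`` seeded from
``SynthParams.seed``: identical parameters and seed reproduce sessions
bit-identically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .preprocess import ForcePlatePair, LfpRecording


@dataclass
class BandOscillation:
    """One narrow-band oscillatory component of the synthetic LFP.

    ``coupling_gain``/``coupling_sign`` set how the band's amplitude
    envelope follows movement intensity: envelope(t) = baseline_amp *
    (1 + sign * gain * intensity(t)), clipped at zero.
    """

    name: str
    center_hz: float
    bandwidth_hz: float
    baseline_amp: float
    coupling_gain: float = 0.0
    coupling_sign: int = 1


def default_band_oscillations() -> list[BandOscillation]:
    """Alpha, beta and low-gamma components with STN-like prominence.

    Only beta is movement-coupled by default (desynchronization, gain 0.8).
    The beta component dominates the oscillatory spectrum — the
    characteristic off-medication parkinsonian STN phenotype — so that even
    with movement-related suppression the session-average beta power
    exceeds that of the uncoupled bands.
    """
    return [
        BandOscillation("alpha", 10.5, 5.0, 0.2),
        BandOscillation("beta", 24.5, 23.0, 0.9,
                        coupling_gain=0.8, coupling_sign=-1),
        BandOscillation("low_gamma", 50.0, 20.0, 0.15),
    ]


@dataclass
class SynthParams:
    """Generator settings for one synthetic participant.

    Defaults describe a ~100-s stepping-in-place session at a comfortable
    0.5 Hz stepping cycle, with slow sinusoidal modulation of stepping
    vigor (participants pace themselves) and a mild visit-to-visit upward
    drift of the aperiodic 1/f exponent (the non-movement-specific spectral
    change the relative features are designed to cancel).
    """

    duration_s: float = 100.0
    step_freq_hz: float = 0.5
    body_weight_n: float = 700.0
    force_fs_hz: int = 100
    lfp_fs_hz: int = 422
    aperiodic_exponent: float = 1.5
    band_oscillations: list[BandOscillation] = field(
        default_factory=default_band_oscillations)
    lfp_noise_sd: float = 0.1
    force_noise_sd_n: float = 5.0
    freeze_episodes: list[tuple[float, float]] = field(default_factory=list)
    amp_modulation_depth: float = 0.5
    amp_modulation_period_s: float = 20.0
    aperiodic_drift_per_visit: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 5:
            raise ValueError("duration_s must exceed 5 s")
        if self.step_freq_hz <= 0:
            raise ValueError("step_freq_hz must be positive")
        if self.force_fs_hz not in (100, 1000):
            raise ValueError("force_fs_hz must be 100 or 1000")
        if self.body_weight_n <= 0:
            raise ValueError("body_weight_n must be positive")
        if not 0 <= self.amp_modulation_depth < 1:
            raise ValueError("amp_modulation_depth must be in [0, 1)")
        for start, end in self.freeze_episodes:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError(
                    f"freeze episode ({start}, {end}) outside "
                    f"[0, {self.duration_s}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freeze_episodes"] = [list(fe) for fe in self.freeze_episodes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        d = dict(d)
        if "band_oscillations" in d:
            d["band_oscillations"] = [
                b if isinstance(b, BandOscillation) else BandOscillation(**b)
                for b in d["band_oscillations"]]
        if "freeze_episodes" in d:
            d["freeze_episodes"] = [tuple(fe) for fe in d["freeze_episodes"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    gait_phase: np.ndarray            # stance in [0,1] on the force grid
    movement_intensity: np.ndarray    # smoothed |d stance/dt| on the LFP grid
    band_envelopes: dict[str, np.ndarray]
    true_coupled_band: str | None


@dataclass
class RawSession:
    """One synthetic visit prior to any preprocessing."""

    lfp: LfpRecording
    force: ForcePlatePair
    visit_index: int
    contacts_id: str
    truth: GroundTruth | None = None
    params: SynthParams | None = None


def _n_samples(duration_s: float, fs: float) -> int:
    # sessions include the endpoint so a 100-s task has labels up to t=100.0
    return int(round(duration_s * fs)) + 1


def _raised_cosine_ramp(t: np.ndarray, start: float, length: float,
                        rising: bool) -> np.ndarray:
    """Smooth 0->1 (rising) or 1->0 ramp over [start, start+length]."""
    x = np.clip((t - start) / length, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * x)
    return ramp if rising else 1.0 - ramp


def gait_waveform(params: SynthParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-sample stance in [0,1] at the force-plate rate.

    0 means full weight on the left plate, 1 full weight on the right,
    0.5 symmetric double support. The waveform is a smoothed square wave
    (raised plateaus emulate single-support phases) whose amplitude is
    slowly modulated; it holds 0.5 during freeze episodes and ramps from/to
    0.5 over the first and last 2 s (quiet standing around the cues).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.force_fs_hz
    t = np.arange(_n_samples(params.duration_s, fs)) / fs

    # stepping phase is locked to the start cue; only vigor drifts
    sq = np.tanh(3.0 * np.sin(2 * np.pi * params.step_freq_hz * t)) \
        / np.tanh(3.0)

    # slow self-paced modulation of stepping vigor
    mod_phase = rng.uniform(0, 2 * np.pi)
    amp = 1.0 - params.amp_modulation_depth * (
        0.5 + 0.5 * np.sin(2 * np.pi * t / params.amp_modulation_period_s
                           + mod_phase))

    envelope = (_raised_cosine_ramp(t, 0.0, 2.0, rising=True)
                * _raised_cosine_ramp(t, params.duration_s - 2.0, 2.0,
                                      rising=False))
    for start, end in params.freeze_episodes:
        # transitions sit just outside the episode so the waveform holds
        # exactly 0.5 throughout [start, end]
        edge = 0.5
        freeze = (_raised_cosine_ramp(t, start - edge, edge, rising=False)
                  + _raised_cosine_ramp(t, end, edge, rising=True))
        envelope = envelope * np.clip(freeze, 0.0, 1.0)

    stance = 0.5 + 0.5 * amp * envelope * sq
    return np.clip(stance, 0.0, 1.0)


def render_forces(stance: np.ndarray, params: SynthParams,
                  rng: np.random.Generator | None = None) -> ForcePlatePair:
    """Map stance onto two noisy vertical-force channels (newtons).

    With zero noise the channels sum to body weight at every sample.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stance = np.asarray(stance, dtype=float)
    if stance.min() < 0 or stance.max() > 1:
        raise ValueError("stance must lie in [0, 1]")
    w = params.body_weight_n
    right = stance * w
    left = (1.0 - stance) * w
    noise = rng.normal(0.0, params.force_noise_sd_n, size=(2, stance.size)) \
        if params.force_noise_sd_n > 0 else np.zeros((2, stance.size))
    samples = np.clip(np.stack([left, right]) + noise, 0.0, None)
    return ForcePlatePair(samples=samples, fs_hz=params.force_fs_hz,
                          body_weight_n=w, provenance=["synthetic"])


def movement_intensity(stance: np.ndarray, fs_hz: float,
                       smooth_s: float = 2.0) -> np.ndarray:
    """|d stance/dt| smoothed with a moving average of ``smooth_s``.

    The 2-s default matches the label's horizon, so band envelopes are
    coupled to exactly the quantity the decoder is asked to predict.
    """
    deriv = np.gradient(np.asarray(stance, dtype=float), 1.0 / fs_hz)
    n = max(1, int(round(smooth_s * fs_hz)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(deriv), kernel, mode="same")


def _aperiodic_noise(n: int, fs: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS colored noise with a 1/f**exponent power spectrum."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    colored = np.fft.irfft(spec * scale, n=n)
    return colored / colored.std()


def _narrowband_carrier(n: int, fs: float, center: float, bandwidth: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise carrier."""
    low = max(0.5, center - bandwidth / 2.0)
    high = min(0.98 * fs / 2.0, center + bandwidth / 2.0)
    sos = signal.butter(2, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    carrier = signal.sosfiltfilt(sos, rng.normal(size=n))
    return carrier / carrier.std()


def render_lfp(stance: np.ndarray, params: SynthParams,
               rng: np.random.Generator | None = None
               ) -> tuple[LfpRecording, GroundTruth]:
    """Render bilateral LFP whose band envelopes follow movement intensity.

    Each channel is 1/f aperiodic noise + sum of enveloped narrow-band
    carriers + white measurement noise. Envelopes are shared across the two
    channels (both STNs see the same behavioral state); carriers and noise
    are independent draws.
    """
    params.validate()
    if not params.band_oscillations:
        raise ValueError("band_oscillations must not be empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.lfp_fs_hz
    n = _n_samples(params.duration_s, fs)
    t_force = np.arange(len(stance)) / params.force_fs_hz
    t_lfp = np.arange(n) / fs
    stance_lfp = np.interp(t_lfp, t_force, np.asarray(stance, dtype=float))
    intensity = movement_intensity(stance_lfp, fs)

    envelopes: dict[str, np.ndarray] = {}
    for band in params.band_oscillations:
        env = band.baseline_amp * (
            1.0 + band.coupling_sign * band.coupling_gain * intensity)
        envelopes[band.name] = np.clip(env, 0.0, None)

    channels = np.zeros((2, n))
    for ch in range(2):
        channels[ch] = _aperiodic_noise(n, fs, params.aperiodic_exponent,
                                        rng)
        for band in params.band_oscillations:
            carrier = _narrowband_carrier(n, fs, band.center_hz,
                                          band.bandwidth_hz, rng)
            channels[ch] += envelopes[band.name] * carrier
        if params.lfp_noise_sd > 0:
            channels[ch] += rng.normal(0.0, params.lfp_noise_sd, size=n)

    coupled = [b for b in params.band_oscillations if b.coupling_gain > 0]
    truth = GroundTruth(
        gait_phase=np.asarray(stance, dtype=float),
        movement_intensity=intensity,
        band_envelopes=envelopes,
        true_coupled_band=max(coupled, key=lambda b: b.coupling_gain).name
        if coupled else None)
    rec = LfpRecording(samples=channels, fs_hz=fs, band_hz="raw",
                       provenance=["synthetic"])
    return rec, truth


def generate_session(params: SynthParams, visit_index: int = 0,
                     contacts_id: str = "contacts-0",
                     rng: np.random.Generator | None = None) -> RawSession:
    """Generate one visit: stance -> forces -> LFP, with ground truth."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stance = gait_waveform(params, rng)
    force = render_forces(stance, params, rng)
    lfp, truth = render_lfp(stance, params, rng)
    return RawSession(lfp=lfp, force=force, visit_index=visit_index,
                      contacts_id=contacts_id, truth=truth, params=params)


def generate_participant(params: SynthParams, n_visits: int = 3,
                         seed: int | None = None) -> list[RawSession]:
    """Generate ``n_visits`` chronologically indexed sessions.

    Visits share the coupling structure and contacts but draw independent
    noise; the aperiodic exponent drifts by ``aperiodic_drift_per_visit``
    per visit, emulating slow non-movement spectral change between visits.
    """
    params.validate()
    if n_visits < 3:
        raise ValueError("need at least 3 visits for the chronological "
                         "train/validation/test split")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    sessions = []
    for v, child in enumerate(root.spawn(n_visits)):
        p = copy.deepcopy(params)
        p.aperiodic_exponent += v * params.aperiodic_drift_per_visit
        rng = np.random.default_rng(child)
        sessions.append(generate_session(p, visit_index=v,
                                         contacts_id="contacts-0", rng=rng))
    return sessions
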