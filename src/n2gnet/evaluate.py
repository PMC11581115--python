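"""Metrics, beta-power baseline, band attribution and group statistics.

Model quality is reported as MAE/MSE on the normalized labels plus the
Kendall tau-b rank correlation between predictions and labels. The
baseline it is compared against is the classic biomarker: 2-s average beta
power (13–36 Hz) from each lead, correlated with the same labels; the lead
with the higher coefficient is the strongest conventional competitor.

Band attribution uses an output-variance probe: the training visit's LFP
is band-pass filtered to each of six bands, run through the trained model,
and the variance of the scalar *before* the final ReLU is collected; the
per-band variances normalized to sum to 1 show which frequency ranges the
trained model's output actually moves with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .model import ModelConfig, N2GNet, VARIANTS, build_model, variant_config
from .preprocess import LfpRecording, bandpass_lfp
from .windows import WindowedDataset

BETA_BAND = (13.0, 36.0)


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float


def default_bands(fs_hz: float = 211.0) -> list[Band]:
    """The six analysis bands; the high-gamma edge tracks 0.95x Nyquist."""
    return [
        Band("delta_theta", 0.5, 8.0),
        Band("alpha", 8.0, 13.0),
        Band("low_beta", 13.0, 20.0),
        Band("high_beta", 20.0, 36.0),
        Band("low_gamma", 36.0, 70.0),
        Band("high_gamma", 70.0, 0.95 * fs_hz / 2.0),
    ]


@dataclass
class EvalReport:
    mae: float
    mse: float
    tau_model: float
    tau_beta_left: float
    tau_beta_right: float

    @property
    def tau_beta_lower(self) -> float:
        return min(self.tau_beta_left, self.tau_beta_right)

    @property
    def tau_beta_higher(self) -> float:
        return max(self.tau_beta_left, self.tau_beta_right)


@dataclass
class VarianceRatioReport:
    """Per-band variance of the hooked pre-ReLU output and its ratio."""

    band_names: list[str]
    variances: np.ndarray
    ratios: np.ndarray

    @property
    def dominant_band(self) -> str:
        return self.band_names[int(np.argmax(self.ratios))]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.band_names, self.ratios.tolist()))


def regression_metrics(predictions: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, float]:
    """(MAE, MSE) of predictions against labels."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.size == 0:
        raise ValueError("empty dataset")
    if predictions.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    err = predictions - labels
    return float(np.abs(err).mean()), float((err ** 2).mean())


def kendall_tau(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.kendalltau(a, b, variant="b").statistic)


def windowed_band_power(lfp: LfpRecording, label_times_s: np.ndarray,
                        band: tuple[float, float] = BETA_BAND,
                        window_s: float = 2.0) -> np.ndarray:
    """Per-lead mean band power over (t−window, t] at each label time.

    Returns an array shaped (2, n_labels): band-pass, square, average —
    the conventional power biomarker computed on the same grid as the
    labels.
    """
    filtered = bandpass_lfp(lfp, band[0], band[1])
    power = filtered.samples ** 2
    n_win = int(round(window_s * lfp.fs_hz))
    end_idx = np.rint(np.asarray(label_times_s) * lfp.fs_hz).astype(int)
    if np.any(end_idx < n_win - 1) or np.any(end_idx > lfp.n_samples - 1):
        raise ValueError("label horizon outside the recording")
    csum = np.concatenate(
        [np.zeros((2, 1)), np.cumsum(power, axis=1)], axis=1)
    return (csum[:, end_idx + 1] - csum[:, end_idx + 1 - n_win]) / n_win


def beta_power_baseline(lfp: LfpRecording, label_times_s: np.ndarray
                        ) -> np.ndarray:
    """2-s average beta power per lead at each label time; shape (2, N)."""
    return windowed_band_power(lfp, label_times_s, BETA_BAND, 2.0)


def eval_report(model: N2GNet, ds: WindowedDataset, lfp: LfpRecording
                ) -> EvalReport:
    """Model metrics plus the per-lead beta-power taus on identical labels."""
    pred = model.predict(ds.inputs)
    mae, mse = regression_metrics(pred, ds.labels)
    beta = beta_power_baseline(lfp, ds.label_times_s)
    return EvalReport(
        mae=mae, mse=mse,
        tau_model=kendall_tau(pred, ds.labels),
        tau_beta_left=kendall_tau(beta[0], ds.labels),
        tau_beta_right=kendall_tau(beta[1], ds.labels))


def variance_ratio(model: N2GNet, training_lfp: LfpRecording,
                   label_times_s: np.ndarray,
                   bands: list[Band] | None = None,
                   window_s: float = 5.0) -> VarianceRatioReport:
    """Fraction of pre-ReLU output variance attributable to each band.

    The training visit's (already canonically filtered) LFP is re-filtered
    to each band, windowed on the label grid, and pushed through the model;
    the variance of the hooked scalar across windows is normalized so the
    six ratios sum to 1.
    """
    if bands is None:
        bands = default_bands(training_lfp.fs_hz)
    if not bands:
        raise ValueError("need at least one band")
    n_win = int(round(window_s * training_lfp.fs_hz))
    end_idx = np.rint(np.asarray(label_times_s)
                      * training_lfp.fs_hz).astype(int)
    end_idx = end_idx[(end_idx >= n_win - 1)
                      & (end_idx <= training_lfp.n_samples - 1)]
    if end_idx.size == 0:
        raise ValueError("no full windows available for attribution")
    variances = np.empty(len(bands))
    for i, band in enumerate(bands):
        filtered = bandpass_lfp(training_lfp, band.low_hz, band.high_hz)
        sw = np.lib.stride_tricks.sliding_window_view(
            filtered.samples, n_win, axis=1)
        wins = sw[:, end_idx - (n_win - 1)].transpose(1, 0, 2)
        variances[i] = float(np.var(model.pre_relu_outputs(wins)))
    total = variances.sum()
    if total <= 0:
        raise ValueError("all band variances are zero; the model output is "
                         "degenerate")
    return VarianceRatioReport(
        band_names=[b.name for b in bands], variances=variances,
        ratios=variances / total)


def run_ablation(datasets: dict, base_config: ModelConfig,
                 train_cfg, variants: list[str] | None = None,
                 verbose: bool = False) -> pd.DataFrame:
    """Train every ablation variant on identical data and seeds.

    ``datasets`` maps 'train'/'validation'/'test' to WindowedDatasets from
    a chronological split. Returns one row per variant with validation and
    test MAE/MSE and Kendall tau.
    """
    from .training import restore_best, train as train_fn

    rows = []
    for name in (variants if variants is not None else list(VARIANTS)):
        cfg = variant_config(name, base_config)
        model = build_model(cfg)
        history = train_fn(model, datasets["train"].inputs,
                           datasets["train"].labels,
                           datasets["validation"].inputs,
                           datasets["validation"].labels, train_cfg,
                           verbose=verbose)
        restore_best(model, history)
        row = {"variant": name, "parameters": model.parameter_count,
               "best_epoch": history.best_epoch,
               "stopped_epoch": history.stopped_epoch}
        for split, tag in (("validation", "val"), ("test", "test")):
            pred = model.predict(datasets[split].inputs)
            mae, mse = regression_metrics(pred, datasets[split].labels)
            row[f"{tag}_mae"] = mae
            row[f"{tag}_mse"] = mse
            row[f"{tag}_tau"] = kendall_tau(pred, datasets[split].labels)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupStatResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool


def mann_whitney_u(a, b, alpha: float = 0.05) -> GroupStatResult:
    """Two-sided Mann-Whitney U for two independent groups."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupStatResult("mann-whitney-u", float(res.statistic),
                           float(res.pvalue), alpha, res.pvalue < alpha)


def wilcoxon_signed_rank(a, b, alpha: float = 0.025) -> GroupStatResult:
    """Two-sided Wilcoxon signed-rank for paired samples.

    The default threshold 0.025 reflects a Bonferroni correction for the
    validation/test pair of comparisons. Identical samples (all zero
    differences) are degenerate and reported as not significant.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    if np.allclose(a, b):
        return GroupStatResult("wilcoxon-signed-rank", float("nan"), 1.0,
                               alpha, False)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return GroupStatResult("wilcoxon-signed-rank", float(res.statistic),
                           float(res.pvalue), alpha, res.pvalue < alpha)


def group_stats(a, b, paired: bool = False,
                alpha: float | None = None) -> GroupStatResult:
    """Dispatch to the appropriate non-parametric two-group test."""
    if paired:
        return wilcoxon_signed_rank(a, b,
                                    0.025 if alpha is None else alpha)
    return mann_whitney_u(a, b, 0.05 if alpha is None else alpha)
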