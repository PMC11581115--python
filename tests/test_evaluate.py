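"""Metrics, Kendall tau oracle, beta-power baseline, band attribution,
group statistics, and the sklearn estimator facade."""

import numpy as np
import pytest

from n2gnet.estimator import N2GNetRegressor
from n2gnet.evaluate import (
    Band,
    beta_power_baseline,
    default_bands,
    group_stats,
    kendall_tau,
    mann_whitney_u,
    regression_metrics,
    variance_ratio,
    wilcoxon_signed_rank,
    windowed_band_power,
)
from n2gnet.model import build_model
from n2gnet.preprocess import LfpRecording


def brute_force_tau_b(a, b):
    """O(n^2) pair counting with the standard tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - ties_a) * (n0 - ties_b))


class TestMetrics:
    def test_perfect_predictions_score_zero(self):
        assert regression_metrics(np.ones(5), np.ones(5)) == (0.0, 0.0)

    def test_constant_error_arithmetic(self):
        mae, mse = regression_metrics(np.full(4, 0.6), np.full(4, 0.5))
        assert mae == pytest.approx(0.1)
        assert mse == pytest.approx(0.01)

    def test_mixed_error_hand_values(self):
        mae, mse = regression_metrics(np.array([0.5, 0.7]),
                                      np.array([0.5, 0.5]))
        assert mae == pytest.approx(0.1)
        assert mse == pytest.approx(0.02)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            regression_metrics(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            regression_metrics(np.ones(3), np.ones(4))


class TestKendallTau:
    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.integers(0, 6, size=20).astype(float)
            b = rng.integers(0, 6, size=20).astype(float)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            assert kendall_tau(a, b) == pytest.approx(
                brute_force_tau_b(a, b), abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            kendall_tau([1.0], [1.0])
        with pytest.raises(ValueError):
            kendall_tau([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBetaPowerBaseline:
    def _lfp(self, freq, fs=211.0, duration=12.0, amp=1.0):
        t = np.arange(int(duration * fs) + 1) / fs
        x = amp * np.sin(2 * np.pi * freq * t)
        return LfpRecording(samples=np.stack([x, x]), fs_hz=fs)

    def test_in_band_tone_mean_square(self):
        # unit 20 Hz sinusoid: mean of sin^2 = 0.5 within filter tolerance
        power = beta_power_baseline(self._lfp(20.0),
                                    np.arange(5.0, 10.0, 0.1))
        assert np.allclose(power, 0.5, rtol=0.05)

    def test_out_of_band_tone_suppressed(self):
        p_in = beta_power_baseline(self._lfp(20.0),
                                   np.arange(5.0, 10.0, 0.1)).mean()
        p_out = beta_power_baseline(self._lfp(50.0),
                                    np.arange(5.0, 10.0, 0.1)).mean()
        assert p_out <= 0.05 * p_in

    def test_rejects_label_before_window_fits(self):
        with pytest.raises(ValueError):
            beta_power_baseline(self._lfp(20.0), np.array([1.0]))


class TestVarianceRatio:
    def _trained_stub(self, tiny_model_config):
        # an untrained (random) model suffices for the normalization
        # invariants; attribution semantics are covered end to end
        return build_model(tiny_model_config)

    def _lfp(self, seed=0, fs=211.0, duration=20.0):
        rng = np.random.default_rng(seed)
        return LfpRecording(
            samples=rng.normal(size=(2, int(duration * fs) + 1)),
            fs_hz=fs, band_hz=(8.0, 100.0))

    def test_ratios_sum_to_one(self, tiny_model_config):
        model = self._trained_stub(tiny_model_config)
        rep = variance_ratio(model, self._lfp(),
                             np.arange(5.0, 20.0, 0.5))
        assert rep.ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(rep.ratios >= 0)

    def test_single_band_is_degenerate_one(self, tiny_model_config):
        model = self._trained_stub(tiny_model_config)
        rep = variance_ratio(model, self._lfp(),
                             np.arange(5.0, 20.0, 0.5),
                             bands=[Band("beta", 13.0, 36.0)])
        assert rep.ratios.tolist() == [1.0]
        assert rep.dominant_band == "beta"

    def test_default_bands_cover_spectrum_in_order(self):
        bands = default_bands(211.0)
        assert [b.name for b in bands] == [
            "delta_theta", "alpha", "low_beta", "high_beta", "low_gamma",
            "high_gamma"]
        for prev, nxt in zip(bands, bands[1:]):
            assert prev.high_hz == nxt.low_hz
        assert bands[-1].high_hz == pytest.approx(0.95 * 211.0 / 2)


class TestGroupStats:
    def test_disjoint_groups_give_u_zero(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.statistic == 0.0
        assert res.significant

    def test_identical_paired_samples_not_significant(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.significant
        assert res.p_value == 1.0

    def test_bonferroni_threshold_applied_to_paired_test(self):
        # a paired p-value of ~0.03 clears 0.05 but not the 0.025 bar
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=12)
            b = a + rng.normal(0.4, 0.5, size=12)
            res = group_stats(a, b, paired=True)
            if 0.025 < res.p_value < 0.05:
                assert not res.significant
                break
        res = group_stats([1, 2, 3], [1, 2, 3], paired=True)
        assert res.alpha == 0.025

    def test_unpaired_dispatch_uses_mann_whitney(self):
        res = group_stats([1, 2, 3, 4], [2, 3, 4, 5], paired=False)
        assert res.test_name == "mann-whitney-u"
        assert res.alpha == 0.05


class TestEstimatorFacade:
    def _toy(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0.5, 2.0, size=n)
        X = rng.normal(size=(n, 2, 64)) * amps[:, None, None]
        return X, (amps ** 2) / 4.0

    def _estimator(self, **kw):
        base = dict(n_filters_per_lead=4, kernel_len=7, pool_len=5,
                    pool_stride=3, se_reduction=2, lstm_hidden=3,
                    head_channels=4, head_kernel_len=3,
                    learning_rate=1e-3, batch_size=8, max_epochs=5,
                    patience_epochs=4, random_state=0)
        base.update(kw)
        return N2GNetRegressor(**base)

    def test_get_set_params_roundtrip_and_clone(self):
        from sklearn.base import clone

        est = self._estimator(use_se=False)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(lstm_hidden=5)
        assert est.lstm_hidden == 5

    def test_fit_predict_shapes_and_nonnegativity(self):
        X, y = self._toy()
        est = self._estimator().fit(X, y)
        pred = est.predict(X)
        assert pred.shape == (30,)
        assert np.all(pred >= 0)
        assert est.n_parameters_ == est.model_.parameter_count
        assert est.best_epoch_ >= 1

    def test_explicit_validation_split_is_respected(self):
        X, y = self._toy()
        est = self._estimator().fit(X[:20], y[:20], X_val=X[20:],
                                    y_val=y[20:])
        assert len(est.validation_scores_) == len(est.loss_curve_)

    def test_flattened_input_layout_accepted(self):
        X, y = self._toy()
        est = self._estimator().fit(X.reshape(30, -1), y)
        p1 = est.predict(X.reshape(30, -1))
        p2 = est.predict(X)
        assert np.allclose(p1, p2)

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            self._estimator().predict(np.zeros((2, 2, 64)))
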