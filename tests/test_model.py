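"""Architecture contracts: gradients, bias audit, ablation lattice,
scale robustness of relative features, and layer-level symmetries."""

import numpy as np
import pytest

from n2gnet.model import (
    ModelConfig,
    VARIANTS,
    build_model,
    variant_config,
)
from n2gnet.nn.layers import BiLSTM, GroupedConv1d, SqueezeExcite


def _features(model, x, stop_before=None):
    """Run the front of the network up to (excluding) a named layer."""
    h = np.asarray(x, dtype=float)
    for name in model._order:
        if name == stop_before:
            break
        h = model.layers[name].forward(h, train=False)
    return h


class TestBuildModel:
    def test_same_seed_builds_identical_parameters(self, tiny_model_config):
        m1 = build_model(tiny_model_config)
        m2 = build_model(tiny_model_config)
        for (n1, p1, _), (n2, p2, _) in zip(m1.named_parameters(),
                                            m2.named_parameters()):
            assert n1 == n2
            assert np.array_equal(p1, p2)

    def test_bias_audit_biases_only_in_se_block(self, tiny_model_config):
        for name in VARIANTS:
            model = build_model(variant_config(name, tiny_model_config))
            assert model.audit_biases(), name
            biases = model.bias_parameter_names()
            if model.config.use_se:
                assert biases and all(b.startswith("se.") for b in biases)
            else:
                assert biases == []

    def test_parameter_count_lattice(self, tiny_model_config):
        count = {name: build_model(variant_config(name,
                                                  tiny_model_config))
                 .parameter_count for name in VARIANTS}
        # removing SE or the bi-LSTM removes parameters
        assert count["N2GNet"] > count["FExt+Bi"]       # no SE
        assert count["N2GNet"] > count["FExt+SE"]       # no bi-LSTM
        assert count["N2GNet"] > count["FExt"]
        # the division block is parameter-free: its removal keeps the count
        assert count["N2GNet"] == count["FExt-Div+SE+Bi"]

    def test_invalid_configs_rejected(self, tiny_model_config):
        cfg = variant_config("N2GNet", tiny_model_config)
        cfg.n_filters_per_lead = 5  # odd: cannot pair numerator/denominator
        with pytest.raises(ValueError):
            build_model(cfg)
        cfg = variant_config("N2GNet", tiny_model_config)
        cfg.se_reduction = 3
        with pytest.raises(ValueError):
            build_model(cfg)
        with pytest.raises(ValueError):
            variant_config("NoSuchModel")


class TestForwardContracts:
    def test_predictions_non_negative_for_random_inputs(self,
                                                        tiny_model_config):
        rng = np.random.default_rng(0)
        for name in VARIANTS:
            model = build_model(variant_config(name, tiny_model_config))
            pred = model.predict(rng.normal(size=(6, 2, 64)) * 10)
            assert np.all(pred >= 0), name

    def test_zero_input_gives_zero_output(self, tiny_model_config):
        for name in VARIANTS:
            model = build_model(variant_config(name, tiny_model_config))
            assert np.allclose(model.predict(np.zeros((3, 2, 64))), 0.0)

    def test_batching_and_duplication_consistency(self, tiny_model_config):
        rng = np.random.default_rng(1)
        model = build_model(tiny_model_config)
        x = rng.normal(size=(2, 64))
        single = model.predict(x[None])
        batch = model.predict(np.stack([x, x, x]))
        assert np.allclose(batch, single[0])

    def test_scalar_output_for_varied_window_lengths(self,
                                                     tiny_model_config):
        rng = np.random.default_rng(2)
        model = build_model(tiny_model_config)
        for length in (48, 64, 100):
            assert model.predict(rng.normal(size=(2, 2, length))).shape \
                == (2,)

    def test_rejects_malformed_windows(self, tiny_model_config):
        model = build_model(tiny_model_config)
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 4, 64)))
        bad = np.zeros((1, 2, 64))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            model.predict(bad)

    def test_relative_features_scale_invariant(self, tiny_model_config):
        # x10 input: original (numerator) power features scale x100 while
        # divided features cancel the scale
        rng = np.random.default_rng(3)
        model = build_model(tiny_model_config)
        x = rng.normal(size=(2, 2, 64))
        f1 = _features(model, x, stop_before="se")
        f2 = _features(model, x * 10.0, stop_before="se")
        F = tiny_model_config.n_filters_per_lead
        half = F // 2
        per_lead = f1.reshape(2, 2, F, -1), f2.reshape(2, 2, F, -1)
        orig1, rel1 = per_lead[0][:, :, :half], per_lead[0][:, :, half:]
        orig2, rel2 = per_lead[1][:, :, :half], per_lead[1][:, :, half:]
        assert np.allclose(orig2, orig1 * 100.0, rtol=1e-9)
        assert np.max(np.abs(rel2 - rel1) / (np.abs(rel1) + 1e-12)) < 0.01

    def test_pre_relu_hook_matches_prediction_through_relu(self,
                                                           tiny_model_config):
        rng = np.random.default_rng(4)
        model = build_model(tiny_model_config)
        x = rng.normal(size=(5, 2, 64))
        pre = model.pre_relu_outputs(x)
        assert np.allclose(np.maximum(pre, 0.0), model.predict(x))


class TestGradients:
    @pytest.mark.parametrize("variant", ["N2GNet", "FExt-Div+SE+Bi",
                                         "FExt+SE", "FExt-Div"])
    def test_backprop_matches_finite_differences(self, variant,
                                                 tiny_model_config):
        rng = np.random.default_rng(7)
        model = build_model(variant_config(variant, tiny_model_config))
        x = rng.normal(size=(3, 2, 40))
        y = rng.uniform(size=3)

        def loss():
            return float(((model.forward(x, train=True) - y) ** 2).mean())

        model.zero_grad()
        pred = model.forward(x, train=True)
        model.backward(2 * (pred - y) / 3)
        checked = 0
        for name, p, grad in model.named_parameters():
            flat = p.reshape(-1)
            gflat = grad.reshape(-1)
            for k in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                eps = 1e-5
                old = flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[k], rel=1e-3, abs=1e-9), \
                    name
                checked += 1
        assert checked >= 12


class TestLayerSymmetries:
    def test_se_gate_bounded_and_contractive(self):
        rng = np.random.default_rng(8)
        se = SqueezeExcite(8, 2, rng)
        x = rng.normal(size=(4, 8, 10)) * 5
        y = se.forward(x)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_se_zero_weights_gate_at_half(self):
        rng = np.random.default_rng(9)
        se = SqueezeExcite(8, 2, rng)
        for layer in (se.encode, se.decode):
            layer.params["weight"][...] = 0.0
            layer.params["bias"][...] = 0.0
        x = rng.normal(size=(2, 8, 5))
        assert np.allclose(se.forward(x), 0.5 * x)

    def test_se_shares_parameters_across_time(self):
        rng = np.random.default_rng(10)
        se = SqueezeExcite(6, 2, rng)
        x = rng.normal(size=(1, 6, 1))
        xx = np.concatenate([x, x], axis=2)
        y = se.forward(xx)
        assert np.allclose(y[..., 0], y[..., 1])

    def test_bilstm_zero_input_zero_output(self):
        rng = np.random.default_rng(11)
        lstm = BiLSTM(4, 3, 3, rng)
        assert np.allclose(lstm.forward(np.zeros((2, 4, 7))), 0.0)

    def test_tied_direction_weights_give_time_reversal_symmetry(self):
        rng = np.random.default_rng(12)
        lstm = BiLSTM(4, 3, 1, rng)
        fwd, bwd = lstm.directions[0]
        for key in ("weight_x", "weight_h"):
            bwd.params[key][...] = fwd.params[key]
        x = rng.normal(size=(2, 4, 9))
        y = lstm.forward(x)
        y_rev = lstm.forward(x[:, :, ::-1].copy())
        H = 3
        assert np.allclose(y_rev[:, :H], y[:, H:][:, :, ::-1], atol=1e-12)

    def test_fft_and_direct_convolution_agree(self):
        rng = np.random.default_rng(13)
        conv_a = GroupedConv1d(2, 8, 11, 2, rng)
        conv_b = GroupedConv1d(2, 8, 11, 2, rng)
        conv_b.params["weight"][...] = conv_a.params["weight"]
        conv_a._FFT_MIN_LEN = 10 ** 9
        conv_b._FFT_MIN_LEN = 0
        x = rng.normal(size=(3, 2, 500))
        ya, yb = conv_a.forward(x), conv_b.forward(x)
        assert np.allclose(ya, yb, atol=1e-10)
        gy = rng.normal(size=ya.shape)
        conv_a.zero_grad()
        conv_b.zero_grad()
        assert np.allclose(conv_a.backward(gy), conv_b.backward(gy),
                           atol=1e-10)
        assert np.allclose(conv_a.grads["weight"], conv_b.grads["weight"],
                           atol=1e-9)

    def test_matched_frequency_kernel_yields_higher_pooled_power(self):
        # hand-set sinusoidal kernel responds more to its own frequency
        rng = np.random.default_rng(14)
        conv = GroupedConv1d(2, 2, 53, 2, rng)
        t = np.arange(53) / 211.0
        conv.params["weight"][...] = np.sin(2 * np.pi * 20 * t)
        tt = np.arange(1055) / 211.0
        matched = np.stack([np.sin(2 * np.pi * 20 * tt)] * 2)[None]
        off = np.stack([np.sin(2 * np.pi * 67 * tt)] * 2)[None]
        p_matched = (conv.forward(matched) ** 2).mean()
        p_off = (conv.forward(off) ** 2).mean()
        assert p_matched > 10 * p_off
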