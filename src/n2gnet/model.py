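"""The neural-to-gait network (N2GNet) and its ablation variants.

The network maps a 5-s window of bilateral STN LFP (2 x 1055 samples at
211 Hz) to a single non-negative weight-shift prediction through four blocks:

1. Feature extraction — depthwise 1-D convolution per lead, batch
   normalization (scale only), exact square activation and average pooling,
   imitating band-power computation; optionally followed by element-wise
   division of half of each lead's power maps by the other half, yielding
   scale-robust *relative* features that are concatenated with the original
   numerators.
2. Feature squeeze-and-excitation — per-time-slice channel gating with
   weights shared across time (the only block with additive biases).
3. A three-layer stacked bidirectional LSTM over the pooled time axis.
4. A regression head: a group-of-2 convolution reads the forward and
   backward LSTM streams with separate kernels, a merging convolution and a
   dense layer collapse them, and a final ReLU guarantees a non-negative
   scalar output.

Removing the division, squeeze-and-excitation and/or bi-LSTM blocks yields
the seven ablation variants evaluated alongside the canonical model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    AvgPool1d,
    BatchNorm1d,
    BiLSTM,
    Dense,
    FeatureDivision,
    GlobalAvgPool1d,
    GroupedConv1d,
    ReLU,
    Square,
    SqueezeExcite,
)

N_LEADS = 2
WINDOW_SAMPLES = 1055  # 5 s at 211 Hz


@dataclass
class ModelConfig:
    """Hyperparameters and ablation flags for the network.

    Defaults correspond to the canonical model at full scale; the ablation
    flags select the seven reduced variants. Sizes not fixed by the
    architecture description are tunable reconstructions.
    """

    use_division: bool = True
    use_se: bool = True
    use_bilstm: bool = True
    n_filters_per_lead: int = 16
    kernel_len: int = 53         # ~0.25 s at 211 Hz
    pool_len: int = 21           # ~0.1 s
    pool_stride: int = 10        # ~0.05 s
    se_reduction: int = 4
    lstm_hidden: int = 32
    lstm_layers: int = 3
    head_channels: int = 16
    head_kernel_len: int = 5
    division_eps: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_filters_per_lead", "kernel_len", "pool_len",
                     "pool_stride", "se_reduction", "lstm_hidden",
                     "lstm_layers", "head_channels", "head_kernel_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.use_division and self.n_filters_per_lead % 2:
            raise ValueError(
                "n_filters_per_lead must be even when use_division is set")
        n_features = N_LEADS * self.n_filters_per_lead
        if self.use_se and n_features % self.se_reduction:
            raise ValueError("feature count not divisible by se_reduction")
        if self.division_eps <= 0:
            raise ValueError("division_eps must be positive")

    @property
    def n_features(self) -> int:
        return N_LEADS * self.n_filters_per_lead

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


#: Ablation variant names mapped to (use_division, use_se, use_bilstm).
#: "FExt" denotes the feature-extraction block *with* division; "-Div"
#: marks its removal.
VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "N2GNet": (True, True, True),
    "FExt-Div+SE+Bi": (False, True, True),
    "FExt-Div+Bi": (False, False, True),
    "FExt-Div+SE": (False, True, False),
    "FExt-Div": (False, False, False),
    "FExt+Bi": (True, False, True),
    "FExt+SE": (True, True, False),
    "FExt": (True, False, False),
}


def variant_config(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Return a config for a named ablation variant, based on ``base``."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from "
                         f"{sorted(VARIANTS)}")
    cfg = copy.deepcopy(base) if base is not None else ModelConfig()
    cfg.use_division, cfg.use_se, cfg.use_bilstm = VARIANTS[name]
    return cfg


class N2GNet:
    """Forward/backward computation graph for one model configuration.

    Parameters are initialized deterministically from ``config.seed``. The
    instance exposes ``state_dict``/``named_parameters`` conveniences so the
    trainer and checkpointing stay simple.
    """

    def __init__(self, config: ModelConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.n_features

        self.layers: dict[str, object] = {}
        self.layers["fext.conv"] = GroupedConv1d(
            N_LEADS, C, config.kernel_len, groups=N_LEADS, rng=rng)
        self.layers["fext.bn"] = BatchNorm1d(C)
        self.layers["fext.square"] = Square()
        self.layers["fext.pool"] = AvgPool1d(config.pool_len,
                                             config.pool_stride)
        if config.use_division:
            self.layers["fext.division"] = FeatureDivision(
                N_LEADS, config.n_filters_per_lead, config.division_eps)
        if config.use_se:
            self.layers["se"] = SqueezeExcite(C, config.se_reduction, rng)
        if config.use_bilstm:
            self.layers["bilstm"] = BiLSTM(C, config.lstm_hidden,
                                           config.lstm_layers, rng)
            head_in = 2 * config.lstm_hidden
            head_groups = 2  # forward / backward streams
        else:
            head_in = C
            head_groups = 1
        hc = config.head_channels
        self.layers["head.conv1"] = GroupedConv1d(
            head_in, head_groups * hc, config.head_kernel_len,
            groups=head_groups, rng=rng)
        self.layers["head.relu1"] = ReLU()
        self.layers["head.conv2"] = GroupedConv1d(
            head_groups * hc, hc, config.head_kernel_len, groups=1, rng=rng)
        self.layers["head.relu2"] = ReLU()
        self.layers["head.gap"] = GlobalAvgPool1d()
        self.layers["head.dense"] = Dense(hc, 1, rng, bias=False)
        # the head input is non-negative (post-ReLU averages), so non-negative
        # final weights keep the output ReLU in its linear region at init
        # instead of starting dead with zero gradient
        np.abs(self.layers["head.dense"].params["weight"],
               out=self.layers["head.dense"].params["weight"])
        self.layers["head.relu_out"] = ReLU()
        self._order = list(self.layers)

    # -- parameter bookkeeping ------------------------------------------

    def _flat_layers(self):
        for name, layer in self.layers.items():
            sub = getattr(layer, "sublayers", None)
            if sub:
                for sname, slayer in sub.items():
                    yield f"{name}.{sname}", slayer
            else:
                yield name, layer

    def named_parameters(self):
        """Yield (name, param, grad) triples over all learnable tensors."""
        for lname, layer in self._flat_layers():
            for pname in layer.params:
                yield (f"{lname}.{pname}", layer.params[pname],
                       layer.grads[pname])

    @property
    def parameter_count(self) -> int:
        return sum(p.size for _, p, _ in self.named_parameters())

    def bias_parameter_names(self) -> list[str]:
        return [n for n, _, _ in self.named_parameters()
                if n.endswith(".bias")]

    def audit_biases(self) -> bool:
        """True iff additive biases exist only inside the SE block."""
        return all(n.startswith("se.") for n in self.bias_parameter_names())

    def zero_grad(self) -> None:
        for _, layer in self._flat_layers():
            layer.zero_grad()

    def state_dict(self) -> dict:
        state = {n: p.copy() for n, p, _ in self.named_parameters()}
        bn = self.layers["fext.bn"]
        state["fext.bn.running_mean"] = bn.running_mean.copy()
        state["fext.bn.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for n, p, _ in self.named_parameters():
            p[...] = state[n]
        bn = self.layers["fext.bn"]
        bn.running_mean[...] = state["fext.bn.running_mean"]
        bn.running_var[...] = state["fext.bn.running_var"]

    # -- computation ----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != N_LEADS:
            raise ValueError("expected windows shaped (batch, 2, length)")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in input windows")
        return x

    def forward(self, x: np.ndarray, train: bool = False,
                return_pre_relu: bool = False) -> np.ndarray:
        """Run the network; returns a (batch,) vector of predictions.

        ``return_pre_relu`` exposes the scalar immediately before the final
        ReLU — the hook used by the frequency-band variance-ratio analysis.
        """
        x = self._check_input(x)
        h = x
        for name in self._order[:-1]:
            h = self.layers[name].forward(h, train=train)
        pre = h[:, 0]
        if return_pre_relu:
            return pre
        return self.layers["head.relu_out"].forward(h, train=train)[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prediction); accumulates grads."""
        g = np.asarray(gy, dtype=float)[:, None]
        for name in reversed(self._order):
            g = self.layers[name].backward(g)

    def predict(self, windows: np.ndarray, batch_size: int = 256
                ) -> np.ndarray:
        """Evaluation-mode predictions (batch norm uses running stats)."""
        x = self._check_input(windows)
        if x.shape[2] < self.config.kernel_len:
            raise ValueError("window shorter than the convolution kernel")
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            out[start:start + batch_size] = self.forward(
                x[start:start + batch_size], train=False)
        return out

    def pre_relu_outputs(self, windows: np.ndarray,
                         batch_size: int = 256) -> np.ndarray:
        """The hooked scalars before the final ReLU, evaluation mode."""
        x = self._check_input(windows)
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            out[start:start + batch_size] = self.forward(
                x[start:start + batch_size], train=False,
                return_pre_relu=True)
        return out

    def describe(self) -> str:
        """Human-readable layer/parameter summary plus the bias audit."""
        lines = [f"{'layer':32s} {'parameters':>12s}"]
        for lname, layer in self._flat_layers():
            n = sum(p.size for p in layer.params.values())
            lines.append(f"{lname:32s} {n:12d}")
        lines.append(f"{'total':32s} {self.parameter_count:12d}")
        audit = "passed" if self.audit_biases() else "FAILED"
        lines.append(f"bias audit (biases only in SE block): {audit}")
        return "\n".join(lines)


def build_model(config: ModelConfig) -> N2GNet:
    """Assemble a network from a configuration (seeded, deterministic)."""
    return N2GNet(config)
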