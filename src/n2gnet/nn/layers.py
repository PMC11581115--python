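"""Layers used by the neural-to-gait network.

Conventions: activations are ``(batch, channels, time)`` float64 arrays except
inside the LSTM, which works on ``(time, batch, features)``. No layer carries
an additive bias unless the architecture explicitly demands one (only the
squeeze-and-excitation block does).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft
from scipy.special import expit


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GroupedConv1d(Layer):
    """1-D convolution with channel groups, no bias, no padding, stride 1.

    ``groups=2`` with one input channel per group is the depthwise front-end
    (each STN lead convolved only with its own kernels); ``groups=1`` is an
    ordinary convolution. Weight shape: (groups, in_per_group, out_per_group,
    kernel_len); output channels are group-major.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_len: int,
                 groups: int, rng: np.random.Generator) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.groups = groups
        self.cin_g = in_channels // groups
        self.cout_g = out_channels // groups
        self.kernel_len = kernel_len
        fan_in = self.cin_g * kernel_len
        self.params["weight"] = _uniform_init(
            rng, (groups, self.cin_g, self.cout_g, kernel_len), fan_in)
        self.zero_grad()

    # direct einsum wins for short sequences; FFT wins for the long
    # front-end convolution over 5-s windows
    _FFT_MIN_LEN = 256

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, T = x.shape
        K = self.kernel_len
        if T < K:
            raise ValueError(f"input length {T} shorter than kernel {K}")
        xg = x.reshape(B, self.groups, self.cin_g, T)
        if T >= self._FFT_MIN_LEN:
            return self._forward_fft(xg, T, K)
        xw = sliding_window_view(xg, K, axis=3)  # (B, G, Cin_g, T', K)
        y = np.einsum("bgctk,gcok->bgot", xw, self.params["weight"],
                      optimize=True)
        self._cache = ("direct", xw)
        return np.ascontiguousarray(y.reshape(B, -1, T - K + 1))

    def _forward_fft(self, xg: np.ndarray, T: int, K: int) -> np.ndarray:
        B = xg.shape[0]
        n = sfft.next_fast_len(T)
        xf = sfft.rfft(xg, n=n, axis=3)            # (B,G,Cin_g,nf)
        wf = sfft.rfft(self.params["weight"], n=n, axis=3)
        # cross-correlation: conjugate the kernel spectrum
        yf = np.einsum("bgcf,gcof->bgof", xf, np.conj(wf), optimize=True)
        y = sfft.irfft(yf, n=n, axis=3)[..., :T - K + 1]
        self._cache = ("fft", xg, xf, n)
        return np.ascontiguousarray(y.reshape(B, -1, T - K + 1))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B = gy.shape[0]
        K = self.kernel_len
        Tp = gy.shape[2]
        gyg = gy.reshape(B, self.groups, self.cout_g, Tp)
        if self._cache[0] == "fft":
            return self._backward_fft(gyg, Tp, K)
        xw = self._cache[1]
        self.grads["weight"] += np.einsum("bgctk,bgot->gcok", xw, gyg,
                                          optimize=True)
        # full correlation of gy with the flipped kernels recovers gx
        gyp = np.zeros((B, self.groups, self.cout_g, Tp + 2 * (K - 1)))
        gyp[..., K - 1:K - 1 + Tp] = gyg
        gyw = sliding_window_view(gyp, K, axis=3)  # (B,G,Cout_g,T,K)
        w_rev = self.params["weight"][..., ::-1]
        gx = np.einsum("bgotk,gcok->bgct", gyw, w_rev, optimize=True)
        return np.ascontiguousarray(gx.reshape(B, -1, Tp + K - 1))

    def _backward_fft(self, gyg: np.ndarray, Tp: int, K: int) -> np.ndarray:
        _, xg, xf, n = self._cache
        B = gyg.shape[0]
        T = Tp + K - 1
        gyf = sfft.rfft(gyg, n=n, axis=3)
        # gw[k] = sum_t x[t+k] gy[t]: correlation of x with gy
        gwf = np.einsum("bgcf,bgof->gcof", xf, np.conj(gyf), optimize=True)
        gw = sfft.irfft(gwf, n=n, axis=3)
        self.grads["weight"] += gw[..., :K]
        # gx[t] = sum_k gy[t-k] w[k]: plain convolution of gy with w
        wf = sfft.rfft(self.params["weight"], n=n, axis=3)
        gxf = np.einsum("bgof,gcof->bgcf", gyf, wf, optimize=True)
        gx = sfft.irfft(gxf, n=n, axis=3)[..., :T]
        return np.ascontiguousarray(gx.reshape(B, -1, T))


class BatchNorm1d(Layer):
    """Per-channel batch normalization with learnable scale and no shift.

    The shift term is an additive bias, which the architecture forbids outside
    the squeeze-and-excitation block, so only ``gamma`` is learned. Running
    statistics are tracked for evaluation mode.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * ivstd[:, None]
        self._cache = (xhat, ivstd, x - mu[:, None], train)
        return self.params["gamma"][:, None] * xhat

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, ivstd, xc, train = self._cache
        self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2))
        gxhat = gy * self.params["gamma"][:, None]
        if not train:
            return gxhat * ivstd[:, None]
        B, C, T = gy.shape
        n = B * T
        gvar = (gxhat * xc).sum(axis=(0, 2)) * (-0.5) * ivstd ** 3
        gmu = -(gxhat.sum(axis=(0, 2))) * ivstd
        gx = (gxhat * ivstd[:, None]
              + (2.0 / n) * gvar[:, None] * xc
              + (gmu / n)[:, None])
        return gx


class Square(Layer):
    """Exact x**2 activation, imitating instantaneous power."""

    def forward(self, x, train=False):
        self._cache = x
        return x * x

    def backward(self, gy):
        return 2.0 * self._cache * gy


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        self._cache = mask
        return x * mask

    def backward(self, gy):
        return gy * self._cache


class AvgPool1d(Layer):
    """Average pooling along time with window ``pool_len``, stride ``stride``."""

    def __init__(self, pool_len: int, stride: int) -> None:
        super().__init__()
        self.pool_len = pool_len
        self.stride = stride

    def forward(self, x, train=False):
        P, S = self.pool_len, self.stride
        if x.shape[-1] < P:
            raise ValueError("input shorter than pooling window")
        xw = sliding_window_view(x, P, axis=-1)[..., ::S, :]
        self._cache = x.shape
        return xw.mean(axis=-1)

    def backward(self, gy):
        P, S = self.pool_len, self.stride
        gx = np.zeros(self._cache)
        Tp = gy.shape[-1]
        idx = S * np.arange(Tp)
        g = gy / P
        for p in range(P):
            gx[..., idx + p] += g
        return gx


class FeatureDivision(Layer):
    """Element-wise division producing relative (aperiodic-robust) features.

    Within each lead's block of ``F`` power maps the first half act as
    numerators and the second half as denominators. The output concatenates
    the original numerators with the divided (relative) features, preserving
    the channel count. The denominator guard ``eps`` keeps the operation
    defined for vanishing power.
    """

    def __init__(self, n_leads: int, filters_per_lead: int,
                 eps: float = 1e-6) -> None:
        super().__init__()
        if filters_per_lead % 2:
            raise ValueError("filters_per_lead must be even for division")
        self.n_leads = n_leads
        self.F = filters_per_lead
        self.eps = eps

    def forward(self, x, train=False):
        B, C, T = x.shape
        xg = x.reshape(B, self.n_leads, self.F, T)
        half = self.F // 2
        num, den = xg[:, :, :half], xg[:, :, half:]
        rel = num / (den + self.eps)
        self._cache = (num, den, rel)
        out = np.concatenate([num, rel], axis=2)
        return out.reshape(B, C, T)

    def backward(self, gy):
        num, den, rel = self._cache
        B, C, T = gy.shape
        half = self.F // 2
        gyg = gy.reshape(B, self.n_leads, self.F, T)
        g_num = gyg[:, :, :half] + gyg[:, :, half:] / (den + self.eps)
        g_den = -gyg[:, :, half:] * rel / (den + self.eps)
        gx = np.concatenate([g_num, g_den], axis=2)
        return gx.reshape(B, C, T)


class Dense(Layer):
    """Linear map on the last axis; bias optional (used only inside SE)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = False) -> None:
        super().__init__()
        self.params["weight"] = _uniform_init(
            rng, (in_features, out_features), in_features)
        if bias:
            self.params["bias"] = np.zeros(out_features)
        self.zero_grad()

    def forward(self, x, train=False):
        self._cache = x
        y = x @ self.params["weight"]
        if "bias" in self.params:
            y = y + self.params["bias"]
        return y

    def backward(self, gy):
        x = self._cache
        self.grads["weight"] += np.einsum("...i,...o->io", x, gy,
                                          optimize=True)
        if "bias" in self.params:
            self.grads["bias"] += gy.reshape(-1, gy.shape[-1]).sum(axis=0)
        return gy @ self.params["weight"].T


class SqueezeExcite(Layer):
    """Per-time-slice channel gating with shared encode/decode weights.

    Each temporal slice of the feature map is squeezed C -> C/r with ReLU and
    excited back to C; a sigmoid turns the decoded vector into gates in (0,1)
    that multiply the input element-wise. This is the only block allowed
    additive biases.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) not divisible by se_reduction "
                f"({reduction})")
        self.encode = Dense(channels, channels // reduction, rng, bias=True)
        self.relu = ReLU()
        self.decode = Dense(channels // reduction, channels, rng, bias=True)

    @property
    def sublayers(self):
        return {"encode": self.encode, "decode": self.decode}

    def zero_grad(self):
        self.encode.zero_grad()
        self.decode.zero_grad()

    def forward(self, x, train=False):
        # (B, C, T) -> slices (B, T, C)
        s = np.ascontiguousarray(np.swapaxes(x, 1, 2))
        z = self.decode.forward(self.relu.forward(self.encode.forward(s)))
        gate = expit(z)
        self._cache = (x, gate)
        return x * np.swapaxes(gate, 1, 2)

    def backward(self, gy):
        x, gate = self._cache
        gate_t = np.swapaxes(gate, 1, 2)
        g_gate = np.swapaxes(gy * x, 1, 2) * gate * (1.0 - gate)
        gs = self.encode.backward(self.relu.backward(
            self.decode.backward(g_gate)))
        return gy * gate_t + np.swapaxes(gs, 1, 2)


class GlobalAvgPool1d(Layer):
    """Mean over time: makes the head's output independent of window length."""

    def forward(self, x, train=False):
        self._cache = x.shape
        return x.mean(axis=-1)

    def backward(self, gy):
        shape = self._cache
        return np.broadcast_to(gy[..., None] / shape[-1], shape).copy()


class LSTMDirection(Layer):
    """One unidirectional biasless LSTM pass over (time, batch, features)."""

    def __init__(self, in_features: int, hidden: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        self.params["weight_x"] = _uniform_init(
            rng, (in_features, 4 * hidden), in_features)
        self.params["weight_h"] = _uniform_init(
            rng, (hidden, 4 * hidden), hidden)
        self.zero_grad()

    def forward(self, xs: np.ndarray, reverse: bool = False,
                train: bool = False) -> np.ndarray:
        T, B, _ = xs.shape
        H = self.hidden
        Wx, Wh = self.params["weight_x"], self.params["weight_h"]
        order = range(T - 1, -1, -1) if reverse else range(T)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        cache = []
        for t in order:
            a = xs[t] @ Wx + h @ Wh
            i = expit(a[:, :H])
            f = expit(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = expit(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            cache.append((t, i, f, g, o, c_prev, h_prev, tc))
        self._cache = (xs, cache, reverse)
        return hs

    def backward(self, ghs: np.ndarray) -> np.ndarray:
        xs, cache, reverse = self._cache
        T, B, _ = xs.shape
        H = self.hidden
        Wx, Wh = self.params["weight_x"], self.params["weight_h"]
        gWx, gWh = self.grads["weight_x"], self.grads["weight_h"]
        gxs = np.zeros_like(xs)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t, i, f, g, o, c_prev, h_prev, tc in reversed(cache):
            dh = ghs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            gWx += xs[t].T @ da
            gWh += h_prev.T @ da
            gxs[t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        return gxs


class BiLSTM(Layer):
    """Stacked bidirectional LSTM; forward/backward streams concatenated."""

    def __init__(self, in_features: int, hidden: int, n_layers: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.n_layers = n_layers
        self.hidden = hidden
        self.directions: list[tuple[LSTMDirection, LSTMDirection]] = []
        feats = in_features
        for _ in range(n_layers):
            fwd = LSTMDirection(feats, hidden, rng)
            bwd = LSTMDirection(feats, hidden, rng)
            self.directions.append((fwd, bwd))
            feats = 2 * hidden

    @property
    def sublayers(self):
        out = {}
        for li, (fwd, bwd) in enumerate(self.directions):
            out[f"layer{li}.forward"] = fwd
            out[f"layer{li}.backward"] = bwd
        return out

    def zero_grad(self):
        for fwd, bwd in self.directions:
            fwd.zero_grad()
            bwd.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # (B, C, T) -> (T, B, C)
        xs = np.ascontiguousarray(np.transpose(x, (2, 0, 1)))
        for fwd, bwd in self.directions:
            hf = fwd.forward(xs, reverse=False)
            hb = bwd.forward(xs, reverse=True)
            xs = np.concatenate([hf, hb], axis=2)
        return np.ascontiguousarray(np.transpose(xs, (1, 2, 0)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        H = self.hidden
        gxs = np.ascontiguousarray(np.transpose(gy, (2, 0, 1)))
        for fwd, bwd in reversed(self.directions):
            gf = fwd.backward(np.ascontiguousarray(gxs[:, :, :H]))
            gb = bwd.backward(np.ascontiguousarray(gxs[:, :, H:]))
            gxs = gf + gb
        return np.ascontiguousarray(np.transpose(gxs, (1, 2, 0)))
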