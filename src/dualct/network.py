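"""Learned components of the dual-domain reconstruction network.

The dual-domain model is two structurally identical single-domain
sub-networks — one refining the bilinearly interpolated sinogram (SDNet),
one refining the reconstructed image (IDNet) — joined by a differentiable
FBP embedding layer.  Each single-domain network decomposes its input
with a two-level Haar transform and restores the three frequency groups
(LV2 low, LV2 high, LV1 high) in separate branches built from recurrent
convolution units (RCU: conv-BN-ReLU followed by one Conv-LSTM cell with
states threaded between successive units), a channel self-attention
residual block on the low branch, and multi-level frequency normalization
fusion (MFNF) blocks with adaptive channel soft thresholding (ACSTF) on
the high branches.  Every branch predicts a residual correction to its
input band, and the band-emitting convolutions are zero-initialized so a
freshly built network is exactly the identity map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .fbp import FBPConfig, fbp_apply, fbp_vjp
from .geometry import ScanGeometry, Sinogram, interpolate_views
from .wavelet import decompose2, reconstruct2, WaveletPyramid


@dataclass
class ModelConfig:
    """Architecture switches; the ablation axes are the three flags."""

    base_channels: int = 32
    use_conv_lstm: bool = True
    use_acstf: bool = True
    fusion_mode: str = "snfm"  # one of {"snfm", "sum", "concat"}
    d_k: Optional[int] = None  # attention key dim; default = channel count of K
    init_seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.fusion_mode not in ("snfm", "sum", "concat"):
            raise ValueError(f"invalid fusion_mode: {self.fusion_mode!r}")
        if self.d_k is not None and self.d_k < 1:
            raise ValueError("d_k must be >= 1")

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("base_channels", "use_conv_lstm", "use_acstf", "fusion_mode",
                 "d_k", "init_seed", "dtype")}


# ---------------------------------------------------------------------------
# module infrastructure
# ---------------------------------------------------------------------------

class Module:
    training = True

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode=True):
        self.training = mode
        for _, c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = b.copy()
        return state

    def named_buffers(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        # buffers (batch-norm running stats) are plain arrays on modules
        for name, _ in self.named_buffers():
            obj, attr = self._resolve(name)
            setattr(obj, attr, np.array(state[name]))

    def _resolve(self, dotted):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        return obj, parts[-1]

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for name, _ in self.named_buffers():
            obj, attr = self._resolve(name)
            setattr(obj, attr, getattr(obj, attr).astype(dtype))
        return self


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, groups=1,
                 bias=True, dtype=np.float32, zero_init=False):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        if zero_init:
            self.weight = Parameter(np.zeros((cout, cin // groups, k, k), dtype))
        else:
            self.weight = Parameter(_he_init(rng, (cout, cin // groups, k, k),
                                             fan_in, dtype))
        self.bias = Parameter(np.zeros(cout, dtype)) if bias else None

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, dtype=np.float32, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(c, dtype))
        self.beta = Parameter(np.zeros(c, dtype))
        self.running_mean = np.zeros(c, dtype)
        self.running_var = np.ones(c, dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        g = self.gamma.reshape(-1, 1, 1)
        b = self.beta.reshape(-1, 1, 1)
        if self.training:
            mu = x.mean(axis=(1, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(-1, 1, 1))
            var = Tensor(self.running_var.reshape(-1, 1, 1))
        return g * (x - mu) * (var + self.eps) ** -0.5 + b


class CBR(Module):
    """conv 3x3 - batch norm - ReLU; integrates features, adjusts channels."""

    def __init__(self, cin, cout, rng, stride=1, dtype=np.float32):
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class DWSepConv(Module):
    """Pointwise (1x1) convolution followed by 3x3 depthwise convolution."""

    def __init__(self, cin, cout, rng, bias=True, dtype=np.float32):
        self.pw = Conv2d(cin, cout, 1, rng, bias=False, dtype=dtype)
        self.dw = Conv2d(cout, cout, 3, rng, groups=cout, bias=bias,
                         dtype=dtype)

    def __call__(self, x):
        return self.dw(self.pw(x))


def avg_pool2(x):
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


# ---------------------------------------------------------------------------
# Conv-LSTM and the recurrent convolution unit
# ---------------------------------------------------------------------------

class ConvLSTMCell(Module):
    """One Conv-LSTM step on the channel concatenation (x, h_prev).

    Gates use the factored "1x1 conv - 3x3 depthwise conv" transform; the
    recurrence is f, i, o = sigmoid(W * (x, h)), c' = tanh(W_c * (x, h)),
    c_t = f . c_prev + i . c', h_t = o . tanh(c_t).
    """

    def __init__(self, channels, rng, dtype=np.float32):
        self.channels = channels
        self.w_f = DWSepConv(2 * channels, channels, rng, dtype=dtype)
        self.w_i = DWSepConv(2 * channels, channels, rng, dtype=dtype)
        self.w_o = DWSepConv(2 * channels, channels, rng, dtype=dtype)
        self.w_c = DWSepConv(2 * channels, channels, rng, dtype=dtype)

    def __call__(self, x, state):
        h_prev, c_prev = state
        xh = ad.concatenate([x, h_prev], axis=0)
        f = self.w_f(xh).sigmoid()
        i = self.w_i(xh).sigmoid()
        o = self.w_o(xh).sigmoid()
        c_new = self.w_c(xh).tanh()
        c = f * c_prev + i * c_new
        h = o * c.tanh()
        return h, (h, c)


class RCU(Module):
    """Recurrent convolution unit: CBR, one Conv-LSTM cell, 3x3 output conv.

    ``state_channels`` declares the channel count of the incoming recurrent
    state (from the previous RCU in the branch); a pointwise projection
    adapts it, and average pooling bridges any spatial downsampling.  With
    ``use_conv_lstm`` False the unit is the plain CBR + output conv path
    (the ablation baseline).
    """

    def __init__(self, cin, cout, rng, stride=1, use_conv_lstm=True,
                 state_channels=None, dtype=np.float32):
        self.cbr = CBR(cin, cout, rng, stride=stride, dtype=dtype)
        self.use_conv_lstm = use_conv_lstm
        self.cout = cout
        if use_conv_lstm:
            self.lstm = ConvLSTMCell(cout, rng, dtype=dtype)
            if state_channels is not None and state_channels != cout:
                self.h_proj = Conv2d(state_channels, cout, 1, rng, dtype=dtype)
                self.c_proj = Conv2d(state_channels, cout, 1, rng, dtype=dtype)
        self.out_conv = Conv2d(cout, cout, 3, rng, dtype=dtype)

    def _adapt_state(self, state, like):
        h, c = state
        while h.shape[-1] > like.shape[-1] or h.shape[-2] > like.shape[-2]:
            h, c = avg_pool2(h), avg_pool2(c)
        if h.shape[0] != like.shape[0]:
            h, c = self.h_proj(h), self.c_proj(c)
        return h, c

    def __call__(self, x, state_in=None):
        y = self.cbr(x)
        if not self.use_conv_lstm:
            return self.out_conv(y), None
        if state_in is None:
            zeros = Tensor(np.zeros(y.shape, dtype=y.data.dtype))
            state = (zeros, zeros)
        else:
            state = self._adapt_state(state_in, y)
        h, state_out = self.lstm(y, state)
        return self.out_conv(h), state_out


class ChannelSelfAttention(Module):
    """Channel-wise self-attention (cross-covariances across channels)."""

    def __init__(self, channels, rng, d_k=None, dtype=np.float32):
        self.q = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.k = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.v = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.d_k = d_k or channels

    def __call__(self, x):
        c, h, w = x.shape
        q = self.q(x).reshape(c, h * w)
        k = self.k(x).reshape(c, h * w)
        v = self.v(x).reshape(c, h * w)
        scores = (q @ k.T) * (1.0 / math.sqrt(self.d_k))
        att = ad.softmax(scores, axis=-1)
        return (att @ v).reshape(c, h, w)


class RCUAttResblock(Module):
    """Four chained RCUs plus channel self-attention, residual to the input.

    The closing 1x1 convolution is zero-initialized so the block starts as
    the identity.
    """

    def __init__(self, channels, rng, use_conv_lstm=True, d_k=None,
                 dtype=np.float32):
        self.rcus = [RCU(channels, channels, rng, use_conv_lstm=use_conv_lstm,
                         dtype=dtype) for _ in range(4)]
        self.att = ChannelSelfAttention(channels, rng, d_k=d_k, dtype=dtype)
        self.out_conv = Conv2d(channels, channels, 1, rng, zero_init=True,
                               dtype=dtype)

    def __call__(self, x, state_in=None):
        y, state = x, state_in
        for rcu in self.rcus:
            y, state = rcu(y, state)
        y = self.att(y)
        return x + self.out_conv(y), state


# ---------------------------------------------------------------------------
# fusion blocks
# ---------------------------------------------------------------------------

class ACSTF(Module):
    """Adaptive channel soft thresholding.

    A squeeze-and-excitation path (1x1 convs on the global average of |x|)
    produces per-channel factors in (0, 1); thresholds tau are those
    factors times GAP(|x|), hence non-negative, and the output is the
    elementwise soft shrinkage of x by tau.
    """

    def __init__(self, channels, rng, reduction=4, dtype=np.float32):
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng, dtype=dtype)
        self.fc2 = Conv2d(hidden, channels, 1, rng, dtype=dtype)

    def thresholds(self, x):
        gap = ad.global_avg_pool(x.abs())
        z = self.fc2(self.fc1(gap).relu())
        return z.sigmoid() * gap

    def __call__(self, x):
        tau = self.thresholds(x)
        return (x - tau).relu() - (-x - tau).relu()


def position_normalize(x, eps=1e-5):
    """Parameter-free position normalization: per-position channel z-score."""
    mu = x.mean(axis=0, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
    return (x - mu) * (var + eps) ** -0.5


class SNFM(Module):
    """Self-attention-based normalization fusion of low into high features.

    Q and K come from the aggregated low-frequency features, V from the
    high-frequency features, all through depthwise-factored convolutions;
    attention is computed across channels.  The attended feature plus the
    high input ("residual attention feature") drives two 3x3 convolutions
    producing modulation maps (gamma, beta) that re-dress the
    position-normalized low features.
    """

    def __init__(self, c_low, channels, rng, d_k=None, dtype=np.float32):
        self.agg3 = Conv2d(c_low, channels, 3, rng, dtype=dtype)
        self.agg1 = Conv2d(channels, channels, 1, rng, dtype=dtype)
        self.q_dw = Conv2d(channels, channels, 3, rng, groups=channels,
                           dtype=dtype)
        self.k_dw = Conv2d(channels, channels, 3, rng, groups=channels,
                           dtype=dtype)
        self.v_dw = Conv2d(channels, channels, 3, rng, groups=channels,
                           dtype=dtype)
        self.gamma_conv = Conv2d(channels, channels, 3, rng, dtype=dtype)
        self.beta_conv = Conv2d(channels, channels, 3, rng, dtype=dtype)
        self.d_k = d_k or channels

    def attention(self, low, high):
        if low.shape[-2:] != high.shape[-2:]:
            raise ValueError("low/high spatial dimensions must match")
        xl = self.agg1(self.agg3(low))
        c, h, w = xl.shape
        q = self.q_dw(xl).reshape(c, h * w)
        k = self.k_dw(xl).reshape(c, h * w)
        v = self.v_dw(high).reshape(high.shape[0], h * w)
        scores = (q @ k.T) * (1.0 / math.sqrt(self.d_k))
        att = ad.softmax(scores, axis=-1)
        return xl, (att @ v).reshape(high.shape[0], h, w)

    def __call__(self, low, high):
        xl, a = self.attention(low, high)
        ar = a + high
        gamma = self.gamma_conv(ar)
        beta = self.beta_conv(ar)
        return gamma * position_normalize(xl) + beta


class MFNF(Module):
    """Multi-level frequency feature fusion with residual high-path carry.

    fusion (SNFM / sum / concat per config) -> ACSTF (or ReLU) -> 3x3 conv,
    added residually to the high-frequency input.
    """

    def __init__(self, c_low, channels, rng, fusion_mode="snfm",
                 use_acstf=True, d_k=None, dtype=np.float32):
        self.fusion_mode = fusion_mode
        self.use_acstf = use_acstf
        if fusion_mode == "snfm":
            self.snfm = SNFM(c_low, channels, rng, d_k=d_k, dtype=dtype)
        elif fusion_mode == "sum":
            # bias-free so zero low features reduce exactly to the high path
            self.low_proj = Conv2d(c_low, channels, 1, rng, bias=False,
                                   dtype=dtype)
        else:  # concat
            self.cat_proj = Conv2d(c_low + channels, channels, 1, rng,
                                   dtype=dtype)
        if use_acstf:
            self.acstf = ACSTF(channels, rng, dtype=dtype)
        self.out_conv = Conv2d(channels, channels, 3, rng, dtype=dtype)

    def __call__(self, high, low):
        if self.fusion_mode == "snfm":
            fused = self.snfm(low, high)
        elif self.fusion_mode == "sum":
            fused = self.low_proj(low) + high
        else:
            fused = self.cat_proj(ad.concatenate([low, high], axis=0))
        act = self.acstf(fused) if self.use_acstf else fused.relu()
        return high + self.out_conv(act)


# ---------------------------------------------------------------------------
# single-domain and dual-domain networks
# ---------------------------------------------------------------------------

class SingleDomainNet(Module):
    """Three-branch wavelet-domain restoration network (SDNet and IDNet).

    Trunk: input -> RCU(C) -> stride-2 RCU(2C) -> stride-2 RCU(4C).
    Low branch: concat(trunk, ll2) -> RCU(8C) -> RCU-Att-Resblock(8C) ->
    output RCU -> residual ll2 correction.  LV2-high branch: stacked level-2
    detail bands, RCU(4C), MFNF fed by the 8C low features.  LV1-high
    branch at half resolution: stacked level-1 bands, RCU(2C), MFNF fed by
    the bilinearly upsampled 12C aggregate of low features.  Recurrent
    states are threaded along each chain; band outputs are zero-initialized
    residual corrections, so the freshly initialized network is an exact
    identity map.
    """

    def __init__(self, cfg: ModelConfig, rng):
        C = cfg.base_channels
        dt = np.dtype(cfg.dtype).type
        lstm = cfg.use_conv_lstm
        kw = dict(use_conv_lstm=lstm, dtype=dt)
        self.cfg = cfg
        self.trunk1 = RCU(1, C, rng, **kw)
        self.trunk2 = RCU(C, 2 * C, rng, stride=2, state_channels=C, **kw)
        self.trunk3 = RCU(2 * C, 4 * C, rng, stride=2, state_channels=2 * C,
                          **kw)
        self.low_entry = RCU(4 * C + 1, 8 * C, rng, state_channels=4 * C, **kw)
        self.resblock = RCUAttResblock(8 * C, rng, use_conv_lstm=lstm,
                                       d_k=cfg.d_k, dtype=dt)
        self.low_out = RCU(8 * C, C, rng, state_channels=8 * C, **kw)
        self.low_emit = Conv2d(C, 1, 3, rng, zero_init=True, dtype=dt)
        self.lv2_rcu = RCU(3, 4 * C, rng, **kw)
        self.lv2_mfnf = MFNF(8 * C, 4 * C, rng, fusion_mode=cfg.fusion_mode,
                             use_acstf=cfg.use_acstf, d_k=cfg.d_k, dtype=dt)
        self.lv2_emit = Conv2d(4 * C, 3, 3, rng, zero_init=True, dtype=dt)
        self.lv1_rcu = RCU(3, 2 * C, rng, **kw)
        self.lv1_mfnf = MFNF(12 * C, 2 * C, rng, fusion_mode=cfg.fusion_mode,
                             use_acstf=cfg.use_acstf, d_k=cfg.d_k, dtype=dt)
        self.lv1_emit = Conv2d(2 * C, 3, 3, rng, zero_init=True, dtype=dt)

    def __call__(self, x):
        squeeze = False
        if len(x.shape) == 2:
            h, w = x.shape
            if h % 4 or w % 4:
                raise ValueError(
                    f"input dimensions must be divisible by 4, got {(h, w)}")
            x = x.reshape(1, h, w)
            squeeze = True
        p = decompose2(x)
        high2 = ad.concatenate([p.lh2, p.hl2, p.hh2], axis=0)
        high1 = ad.concatenate([p.lh1, p.hl1, p.hh1], axis=0)

        t, s = self.trunk1(x)
        t, s = self.trunk2(t, s)
        t, s = self.trunk3(t, s)
        low, s = self.low_entry(ad.concatenate([t, p.ll2], axis=0), s)
        low, s = self.resblock(low, s)
        low_head, _ = self.low_out(low, s)
        ll2_hat = p.ll2 + self.low_emit(low_head)

        h2, _ = self.lv2_rcu(high2)
        f2 = self.lv2_mfnf(h2, low)
        high2_hat = high2 + self.lv2_emit(f2)

        h1, _ = self.lv1_rcu(high1)
        low12 = ad.concatenate(
            [ad.upsample2_bilinear(low), ad.upsample2_bilinear(f2)], axis=0)
        f1 = self.lv1_mfnf(h1, low12)
        high1_hat = high1 + self.lv1_emit(f1)

        out = reconstruct2(WaveletPyramid(
            ll2_hat, high2_hat[0:1], high2_hat[1:2], high2_hat[2:3],
            high1_hat[0:1], high1_hat[1:2], high1_hat[2:3],
            p.height, p.width))
        if squeeze:
            out = out.reshape(out.shape[-2], out.shape[-1])
        return out


def fbp_embedding(s: Tensor, view_angles, geom: ScanGeometry,
                  cfg: FBPConfig) -> Tensor:
    """Differentiable FBP layer: linear forward, exact-transpose backward."""
    s = ad.as_tensor(s)
    img = fbp_apply(s.data, view_angles, geom, cfg).astype(s.data.dtype)
    out = ad._node(img, (s,))
    if out._parents:
        out._backward = lambda g: (
            fbp_vjp(g, view_angles, geom, cfg).astype(s.data.dtype),)
    return out


class DualDomainNet(Module):
    """SDNet -> FBP embedding layer -> IDNet around a sparse-view sinogram.

    ``stub=True`` bypasses both sub-networks, so the image output equals
    the FBP of the view-interpolated sinogram exactly (the consistency
    anchor for the learned path).
    """

    def __init__(self, cfg: ModelConfig, geom: ScanGeometry,
                 fbp_cfg: FBPConfig, stub: bool = False):
        rng = np.random.default_rng(cfg.init_seed)
        self.cfg = cfg
        self.geom = geom
        self.fbp_cfg = fbp_cfg
        self.stub = stub
        self.sdnet = SingleDomainNet(cfg, rng)
        self.idnet = SingleDomainNet(cfg, rng)

    def __call__(self, sparse: Sinogram):
        if sparse.values.shape[1] != self.geom.n_detectors:
            raise ValueError("sinogram does not match the model geometry")
        if self.geom.n_views_full % sparse.n_views:
            raise ValueError("sparse view count must divide the full count")
        interp = interpolate_views(sparse, self.geom.n_views_full)
        x = Tensor(interp.values.astype(self.cfg.dtype))
        if self.stub:
            s_ref = x
            img = fbp_embedding(s_ref, interp.view_angles, self.geom,
                                self.fbp_cfg)
            return s_ref, img
        s_hat = self.sdnet(x)
        img0 = fbp_embedding(s_hat, interp.view_angles, self.geom,
                             self.fbp_cfg)
        i_hat = self.idnet(img0)
        return s_hat, i_hat
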