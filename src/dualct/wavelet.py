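"""Two-level 2-D Haar wavelet decomposition and its exact inverse.

The analysis bank applies the four directional 2x2 Haar kernels

    f_LL = [[ 1,  1], [ 1,  1]]     f_LH = [[-1, -1], [ 1,  1]]
    f_HL = [[-1,  1], [-1,  1]]     f_HH = [[ 1, -1], [-1,  1]]

non-overlapping with stride 2, each scaled by 1/2 (orthonormal Haar), so
the same bank synthesizes and the transform is an isometry: round trips
are exact and energy is conserved.  The first kernel index is the row
(vertical) axis, so f_LH responds to vertical variation (horizontal-edge
detail).  All routines accept plain numpy arrays or autodiff tensors with
the two trailing axes spatial, which is how the sub-networks run the
transform differentiably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The four analysis kernels, including the orthonormal 1/2 scaling.
HAAR_KERNELS = {
    "ll": 0.5 * np.array([[1.0, 1.0], [1.0, 1.0]]),
    "lh": 0.5 * np.array([[-1.0, -1.0], [1.0, 1.0]]),
    "hl": 0.5 * np.array([[-1.0, 1.0], [-1.0, 1.0]]),
    "hh": 0.5 * np.array([[1.0, -1.0], [-1.0, 1.0]]),
}


def _check_even(shape):
    if shape[-2] % 2 or shape[-1] % 2:
        raise ValueError(f"spatial dimensions must be even, got {shape[-2:]}")


def dwt2(x):
    """One analysis level: returns (ll, lh, hl, hh), each at half resolution."""
    _check_even(x.shape)
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (-a - b + c + d) * 0.5
    hl = (-a + b - c + d) * 0.5
    hh = (a - b - c + d) * 0.5
    return ll, lh, hl, hh


def idwt2(ll, lh, hl, hh):
    """Exact inverse of :func:`dwt2`."""
    shapes = {tuple(t.shape) for t in (ll, lh, hl, hh)}
    if len(shapes) != 1:
        raise ValueError(f"band shape mismatch: {sorted(shapes)}")
    a = (ll - lh - hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    c = (ll + lh - hl - hh) * 0.5
    d = (ll + lh + hl + hh) * 0.5
    return _interleave2(a, b, c, d)


def _interleave2(a, b, c, d):
    """Reassemble stride-2 polyphase components into the full-size array."""
    if isinstance(a, np.ndarray):
        h, w = a.shape[-2], a.shape[-1]
        out = np.empty(a.shape[:-2] + (2 * h, 2 * w), dtype=a.dtype)
        out[..., 0::2, 0::2] = a
        out[..., 0::2, 1::2] = b
        out[..., 1::2, 0::2] = c
        out[..., 1::2, 1::2] = d
        return out
    # autodiff path: build by summing zero-padded slices is wasteful; use
    # reshape-based interleaving instead (differentiable through reshape
    # and concatenate)
    from . import autodiff as ad
    h, w = a.shape[-2], a.shape[-1]
    top = ad.concatenate(
        [a.reshape(a.shape + (1,)), b.reshape(b.shape + (1,))], axis=-1
    ).reshape(a.shape[:-1] + (2 * w,))
    bot = ad.concatenate(
        [c.reshape(c.shape + (1,)), d.reshape(d.shape + (1,))], axis=-1
    ).reshape(c.shape[:-1] + (2 * w,))
    rows = ad.concatenate(
        [top.reshape(top.shape[:-2] + (h, 1, 2 * w)),
         bot.reshape(bot.shape[:-2] + (h, 1, 2 * w))], axis=-2
    )
    return rows.reshape(a.shape[:-2] + (2 * h, 2 * w))


@dataclass
class WaveletPyramid:
    """Two-level Haar band set of an image- or sinogram-shaped array."""

    ll2: object
    lh2: object
    hl2: object
    hh2: object
    lh1: object
    hl1: object
    hh1: object
    height: int
    width: int


def decompose2(x) -> WaveletPyramid:
    """Two-level decomposition; spatial dims must be divisible by 4."""
    h, w = x.shape[-2], x.shape[-1]
    if h % 4 or w % 4:
        raise ValueError(f"dimensions must be divisible by 4, got {(h, w)}")
    ll1, lh1, hl1, hh1 = dwt2(x)
    ll2, lh2, hl2, hh2 = dwt2(ll1)
    return WaveletPyramid(ll2, lh2, hl2, hh2, lh1, hl1, hh1, h, w)


def reconstruct2(p: WaveletPyramid):
    """Exact inverse of :func:`decompose2`."""
    ll1 = idwt2(p.ll2, p.lh2, p.hl2, p.hh2)
    return idwt2(ll1, p.lh1, p.hl1, p.hh1)
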