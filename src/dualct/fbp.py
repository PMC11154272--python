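"""Fan-beam filtered back-projection for a flat, equidistant detector.

Classic weighted-filter-backproject scheme: detector samples are rescaled
to a virtual detector through the isocenter, cosine pre-weighted, ramp
(Ram-Lak) filtered along the detector axis in the frequency domain with
zero-padding, and back-projected with inverse-square distance weighting
and linear detector interpolation.  The whole chain is linear in the
sinogram, and :func:`fbp_vjp` applies its exact transpose, which is what
the differentiable reconstruction layer between the two sub-networks
needs for gradient flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ImageGrid, ScanGeometry, Sinogram, default_pixel_size


@dataclass(frozen=True)
class FBPConfig:
    image_size: int
    pixel_size: Optional[float] = None
    filter_kind: str = "ramp"
    padding: Optional[int] = None  # FFT length; default next pow2 >= 2*n_det

    def __post_init__(self):
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.filter_kind != "ramp":
            raise ValueError(f"unknown filter: {self.filter_kind!r}")


def _ramp_kernel(n_det: int, tau: float) -> np.ndarray:
    """Band-limited spatial-domain Ram-Lak kernel, center at index n_det-1."""
    n = np.arange(-(n_det - 1), n_det)
    h = np.zeros(n.shape, dtype=np.float64)
    h[n == 0] = 1.0 / (4.0 * tau * tau)
    odd = n % 2 == 1
    h[odd] = -1.0 / (np.pi * n[odd] * tau) ** 2
    return h


def _fft_len(cfg: FBPConfig, n_det: int) -> int:
    if cfg.padding is not None:
        return int(cfg.padding)
    return int(2 ** np.ceil(np.log2(2 * n_det)))


def _filter_rows(rows: np.ndarray, kernel: np.ndarray, nfft: int,
                 n_det: int) -> np.ndarray:
    """Linear convolution with the centered kernel, output aligned to input."""
    kf = np.fft.rfft(kernel, nfft)
    rf = np.fft.rfft(rows, nfft, axis=1)
    full = np.fft.irfft(rf * kf[None, :], nfft, axis=1)
    return full[:, n_det - 1:2 * n_det - 1]


def _filter_rows_adjoint(rows: np.ndarray, kernel: np.ndarray, nfft: int,
                         n_det: int) -> np.ndarray:
    """Exact transpose of :func:`_filter_rows` as a linear map."""
    kf = np.fft.rfft(kernel, nfft)
    emb = np.zeros((rows.shape[0], nfft), dtype=np.float64)
    emb[:, n_det - 1:2 * n_det - 1] = rows
    full = np.fft.irfft(np.fft.rfft(emb, axis=1) * np.conj(kf)[None, :],
                        nfft, axis=1)
    return full[:, :n_det]


def _prep(s_shape, geom: ScanGeometry, cfg: FBPConfig):
    n_views, n_det = s_shape
    if n_det != geom.n_detectors:
        raise ValueError("detector count mismatch between sinogram and geometry")
    sid = geom.source_to_isocenter
    scale = sid / geom.source_to_detector
    tau = geom.detector_pitch * scale  # virtual detector pitch at isocenter
    t = (np.arange(n_det) - (n_det - 1) / 2.0) * tau
    cosw = sid / np.sqrt(sid * sid + t * t)
    kernel = _ramp_kernel(n_det, tau)
    nfft = _fft_len(cfg, n_det)
    px = cfg.pixel_size if cfg.pixel_size is not None else \
        default_pixel_size(geom, cfg.image_size)
    half = (cfg.image_size - 1) / 2.0
    xs = (np.arange(cfg.image_size) - half) * px
    # pixel [r, c] sits at y = (r - half) * px, x = (c - half) * px, the same
    # convention as the forward projector
    Y = np.broadcast_to(xs[:, None], (cfg.image_size, cfg.image_size)).copy()
    X = np.broadcast_to(xs[None, :], (cfg.image_size, cfg.image_size)).copy()
    return n_views, n_det, sid, tau, cosw, kernel, nfft, px, X, Y


def _view_coords(beta, X, Y, sid, tau, n_det):
    cb, sb = np.cos(beta), np.sin(beta)
    L = sid - (X * cb + Y * sb)  # distance along the central-ray axis
    tdet = sid * (-X * sb + Y * cb) / L
    u = tdet / tau + (n_det - 1) / 2.0
    U2 = (L / sid) ** 2
    return u, U2


def fbp_apply(values: np.ndarray, view_angles: np.ndarray, geom: ScanGeometry,
              cfg: FBPConfig) -> np.ndarray:
    """FBP as a raw linear map on a (n_views, n_detectors) array (float64)."""
    values = np.asarray(values)
    n_views, n_det, sid, tau, cosw, kernel, nfft, px, X, Y = _prep(
        values.shape, geom, cfg)
    q = _filter_rows(values.astype(np.float64) * cosw[None, :],
                     kernel, nfft, n_det) * tau
    dbeta = np.deg2rad(geom.angular_span) / n_views
    betas = np.deg2rad(view_angles)
    acc = np.zeros_like(X)
    for k, beta in enumerate(betas):
        u, U2 = _view_coords(beta, X, Y, sid, tau, n_det)
        u0 = np.floor(u).astype(np.intp)
        f = u - u0
        row = q[k]
        v = np.zeros_like(u)
        for du, w in ((0, 1.0 - f), (1, f)):
            uu = u0 + du
            ok = (uu >= 0) & (uu < n_det)
            v[ok] += w[ok] * row[uu[ok]]
        acc += v / U2
    acc *= 0.5 * dbeta
    return acc


def fbp_reconstruct(s: Sinogram, geom: ScanGeometry, cfg: FBPConfig) -> ImageGrid:
    """Reconstruct an attenuation image from a fan-beam sinogram."""
    acc = fbp_apply(s.values, s.view_angles, geom, cfg)
    px = cfg.pixel_size if cfg.pixel_size is not None else \
        default_pixel_size(geom, cfg.image_size)
    return ImageGrid(acc.astype(np.float32), px)


def fbp_vjp(upstream: np.ndarray, view_angles: np.ndarray, geom: ScanGeometry,
            cfg: FBPConfig) -> np.ndarray:
    """Transpose of the discrete FBP operator applied to an image gradient.

    Returns a (n_views, n_detectors) array; together with
    :func:`fbp_reconstruct` it satisfies the adjoint identity
    <FBP(s), y> = <s, fbp_vjp(y)>.
    """
    upstream = np.asarray(upstream, dtype=np.float64)
    if upstream.shape != (cfg.image_size, cfg.image_size):
        raise ValueError("upstream gradient shape mismatch")
    n_views = len(view_angles)
    _, n_det, sid, tau, cosw, kernel, nfft, px, X, Y = _prep(
        (n_views, geom.n_detectors), geom, cfg)
    dbeta = np.deg2rad(geom.angular_span) / n_views
    betas = np.deg2rad(view_angles)
    dq = np.zeros((n_views, n_det), dtype=np.float64)
    for k, beta in enumerate(betas):
        u, U2 = _view_coords(beta, X, Y, sid, tau, n_det)
        g = 0.5 * dbeta * upstream / U2
        u0 = np.floor(u).astype(np.intp)
        f = u - u0
        for du, w in ((0, 1.0 - f), (1, f)):
            uu = u0 + du
            ok = (uu >= 0) & (uu < n_det)
            np.add.at(dq[k], uu[ok], (w * g)[ok])
    ds = _filter_rows_adjoint(dq * tau, kernel, nfft, n_det) * cosw[None, :]
    return ds
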