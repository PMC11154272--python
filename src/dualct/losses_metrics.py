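"""Training losses and image-quality metrics.

The training objective is L = MAE(sinogram) + MSE(image) + alpha * L_edge,
where the edge term is the mean absolute difference of the two images
after filtering with a discrete 5x5 Laplacian-of-Gaussian kernel — a
second-derivative operator that penalizes disagreement at edges and
counteracts the over-smoothing bias of plain MSE.  Evaluation metrics are
the field's standard PSNR / SSIM / RMSE / rRMSE plus the first-difference
sharpness measures AG (average gradient) and SF (spatial frequency).
SSIM here is the global (whole-image statistics) form of the similarity
index, not the windowed variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoGKernel:
    """Discrete 5x5 Laplacian-of-Gaussian kernel (DC-corrected)."""

    kernel: np.ndarray
    sigma: float


def log_kernel(size: int = 5, sigma: float = 1.0) -> LoGKernel:
    """Sample the LoG  -1/(pi s^4) (1 - r^2/(2 s^2)) exp(-r^2/(2 s^2))
    on an odd grid and subtract the mean so the kernel sums to zero."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    X, Y = np.meshgrid(x, x)
    r2 = (X ** 2 + Y ** 2) / (2.0 * sigma ** 2)
    k = -1.0 / (np.pi * sigma ** 4) * (1.0 - r2) * np.exp(-r2)
    k = k - k.mean()
    return LoGKernel(k, sigma)


def edge_loss(img, ref, k: Optional[LoGKernel] = None) -> Tensor:
    """Mean absolute difference of the LoG-filtered images (differentiable)."""
    if k is None:
        k = log_kernel()
    img = ad.as_tensor(img)
    ref = ad.as_tensor(ref)
    if img.shape != ref.shape:
        raise ValueError("image shapes must match")
    w = Tensor(k.kernel[None, None].astype(img.data.dtype))
    pad = k.kernel.shape[0] // 2
    ei = ad.conv2d(img.reshape(1, *img.shape), w, padding=pad)
    er = ad.conv2d(ref.reshape(1, *ref.shape), w, padding=pad)
    return (ei - er).abs().mean()


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.02  # edge-loss weight
    sigma: float = 1.0   # LoG sigma in pixels

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def total_loss(s, s_ref, img, img_ref, cfg: LossConfig = LossConfig()) -> Tensor:
    """L = MAE(S, S_ref) + MSE(I, I_ref) + alpha * L_edge(I, I_ref)."""
    s = ad.as_tensor(s)
    s_ref = ad.as_tensor(s_ref)
    img = ad.as_tensor(img)
    img_ref = ad.as_tensor(img_ref)
    if s.shape != s_ref.shape or img.shape != img_ref.shape:
        raise ValueError("shape mismatch between prediction and reference")
    l_sino = (s - s_ref).abs().mean()
    l_img = ((img - img_ref) ** 2).mean()
    l_edge = edge_loss(img, img_ref, log_kernel(5, cfg.sigma))
    return l_sino + l_img + cfg.alpha * l_edge


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    psnr: float
    ssim: float
    rmse: float
    rrmse: float  # percent
    ag: float
    sf: float

    def to_dict(self):
        return {k: float(getattr(self, k)) for k in
                ("psnr", "ssim", "rmse", "rrmse", "ag", "sf")}


def normalize_window(img: np.ndarray, window) -> np.ndarray:
    """Linear map of an attenuation window onto [0, 1], clipped."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    return np.clip((np.asarray(img, dtype=np.float64) - lo) / (hi - lo), 0, 1)


def rmse(img, ref) -> float:
    d = np.asarray(img, dtype=np.float64) - np.asarray(ref, dtype=np.float64)
    return float(np.sqrt((d ** 2).mean()))


def rrmse(img, ref) -> float:
    """Relative root-mean-square error against the reference norm, percent."""
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    return float(np.linalg.norm(img - ref) / np.linalg.norm(ref) * 100.0)


def psnr(img, ref) -> float:
    """20 log10(MAX / RMSE) with MAX the maximum over both images."""
    e = rmse(img, ref)
    if e == 0:
        return float("inf")
    mx = max(float(np.max(img)), float(np.max(ref)))
    return float(20.0 * np.log10(mx / e))


def ssim(img, ref, data_range: Optional[float] = None) -> float:
    """Global structural similarity (whole-image population statistics)."""
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if data_range is None:
        data_range = float(max(img.max(), ref.max()) -
                           min(img.min(), ref.min())) or 1.0
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_i, mu_r = img.mean(), ref.mean()
    var_i, var_r = img.var(), ref.var()
    cov = ((img - mu_i) * (ref - mu_r)).mean()
    return float((2 * mu_i * mu_r + c1) * (2 * cov + c2)
                 / ((mu_i ** 2 + mu_r ** 2 + c1) * (var_i + var_r + c2)))


def average_gradient(img) -> float:
    """Mean over pixels of sqrt((d_row^2 + d_col^2) / 2), first differences."""
    img = np.asarray(img, dtype=np.float64)
    dr = img[1:, :-1] - img[:-1, :-1]
    dc = img[:-1, 1:] - img[:-1, :-1]
    return float(np.sqrt((dr ** 2 + dc ** 2) / 2.0).mean())


def spatial_frequency(img) -> float:
    """sqrt(RF^2 + CF^2) with RF/CF the RMS of row/column first differences."""
    img = np.asarray(img, dtype=np.float64)
    rf2 = ((img[:, 1:] - img[:, :-1]) ** 2).mean()
    cf2 = ((img[1:, :] - img[:-1, :]) ** 2).mean()
    return float(np.sqrt(rf2 + cf2))


def compute_metrics(img, ref, data_range: Optional[float] = None
                    ) -> MetricsReport:
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if img.shape != ref.shape:
        raise ValueError("image shapes must match")
    if data_range is not None and data_range <= 0:
        raise ValueError("data_range must be positive")
    return MetricsReport(
        psnr=psnr(img, ref),
        ssim=ssim(img, ref, data_range),
        rmse=rmse(img, ref),
        rrmse=rrmse(img, ref),
        ag=average_gradient(img),
        sf=spatial_frequency(img),
    )


def aggregate_metrics(reports) -> dict:
    """Mean and standard deviation per metric over a list of reports."""
    keys = ("psnr", "ssim", "rmse", "rrmse", "ag", "sf")
    out = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=np.float64)
        out[k] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return out
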