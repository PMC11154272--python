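"""Fan-beam acquisition geometry, the discrete projector and the noise model.

The scanner is a rotating source with a flat, equidistant detector array.
View ``k`` places the source at angle ``k * angular_span / n_views_full``
degrees counterclockwise from the +x axis of the image frame; the rotation
isocenter coincides with the image center.  Projection values are line
integrals of linear attenuation (units: attenuation * mm), evaluated by
sampling each source->detector ray at a fixed step with bilinear image
interpolation.  The matching back-projector is the exact transpose of the
discrete forward operator (same sample points, bilinear scatter instead of
gather), which the differentiable reconstruction layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam acquisition constants (distances in mm, angles in degrees)."""

    n_views_full: int = 512
    angular_span: float = 360.0
    source_to_detector: float = 1280.0
    source_to_isocenter: float = 640.0
    n_detectors: int = 720
    detector_pitch: float = 1.0

    def __post_init__(self):
        if not (0 < self.source_to_isocenter < self.source_to_detector):
            raise ValueError("require 0 < source_to_isocenter < source_to_detector")
        if self.n_detectors <= 0 or self.n_views_full <= 0:
            raise ValueError("detector and view counts must be positive")
        if self.detector_pitch <= 0:
            raise ValueError("detector_pitch must be positive")

    @property
    def view_angles(self) -> np.ndarray:
        """Uniform view angles in degrees, first angle 0."""
        return np.arange(self.n_views_full) * (self.angular_span / self.n_views_full)

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_isocenter

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the field of view inscribed in the fan at isocenter."""
        return 0.5 * self.n_detectors * self.detector_pitch / self.magnification

    def detector_offsets(self) -> np.ndarray:
        """Lateral detector-element center offsets (mm) on the physical detector."""
        n = self.n_detectors
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_pitch

    def with_views(self, n_views: int) -> "ScanGeometry":
        return replace(self, n_views_full=n_views)


def default_pixel_size(geom: ScanGeometry, image_size: int) -> float:
    """Pixel size that inscribes the fan's field of view in the image."""
    return 2.0 * geom.fov_radius / image_size


@dataclass
class ImageGrid:
    """Square map of linear attenuation per mm, centered on the isocenter."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("image must be a square 2-D array")
        if self.pixels.size == 0:
            raise ValueError("image must be non-empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image values must be finite")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class Sinogram:
    """views x detectors array of line integrals tied to a geometry."""

    values: np.ndarray
    view_angles: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.view_angles = np.asarray(self.view_angles, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2-D (views x detectors)")
        if self.values.shape[0] != self.view_angles.shape[0]:
            raise ValueError("row count must equal number of view angles")
        if self.values.shape[1] != self.geometry.n_detectors:
            raise ValueError("column count must equal geometry.n_detectors")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NoiseParams:
    """Mixed Gaussian + Poisson photon-noise parameters."""

    i0: float = 5.0e6
    gauss_mean: float = 0.0
    gauss_var: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")
        if self.gauss_var < 0:
            raise ValueError("gauss_var must be non-negative")


# ---------------------------------------------------------------------------
# bilinear gather / scatter (the transpose pair behind A and A^T)
# ---------------------------------------------------------------------------

def _bilinear_gather(img: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    n = img.shape[0]
    m = img.shape[1]
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    fr = r - r0
    fc = c - c0
    out = np.zeros(r.shape, dtype=np.float64)
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                      (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < m)
        out[ok] += w[ok] * img[rr[ok], cc[ok]]
    return out


def _bilinear_scatter(shape, r, c, vals) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    fr = r - r0
    fc = c - c0
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                      (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.add.at(out, (rr[ok], cc[ok]), w[ok] * vals[ok])
    return out


def _ray_samples(geom: ScanGeometry, beta: float, pixel_size: float,
                 image_size: int, step: float):
    """Pixel-space sample coordinates along every detector ray of one view."""
    sid = geom.source_to_isocenter
    sdd = geom.source_to_detector
    e_s = np.array([np.cos(beta), np.sin(beta)])
    e_p = np.array([-np.sin(beta), np.cos(beta)])
    src = sid * e_s
    det = src - sdd * e_s + geom.detector_offsets()[:, None] * e_p[None, :]
    d = det - src[None, :]
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # sample a window of radius R_s around the point of closest approach
    r_s = image_size * pixel_size / np.sqrt(2.0) + step
    tau_mid = -(src[None, :] * d).sum(axis=1)
    n_s = int(np.ceil(2.0 * r_s / step)) + 1
    tau = tau_mid[:, None] + (np.arange(n_s) - (n_s - 1) / 2.0)[None, :] * step
    pts = src[None, None, :] + d[:, None, :] * tau[:, :, None]
    half = (image_size - 1) / 2.0
    cols = pts[..., 0] / pixel_size + half
    rows = pts[..., 1] / pixel_size + half
    return rows, cols


def forward_project(image: ImageGrid, geom: ScanGeometry,
                    step_ratio: float = 0.5) -> Sinogram:
    """Discrete fan-beam projector A: line integrals of attenuation.

    Each ray is sampled at ``step_ratio * pixel_size`` with bilinear image
    interpolation; the integral is the sample sum times the step.
    """
    n = image.size
    step = step_ratio * image.pixel_size
    img = image.pixels.astype(np.float64)
    betas = np.deg2rad(geom.view_angles)
    out = np.empty((geom.n_views_full, geom.n_detectors), dtype=np.float32)
    for k, beta in enumerate(betas):
        rows, cols = _ray_samples(geom, beta, image.pixel_size, n, step)
        out[k] = (_bilinear_gather(img, rows, cols).sum(axis=1) * step)
    return Sinogram(out, geom.view_angles, geom)


def back_project(s: Sinogram, geom: ScanGeometry, image_size: int,
                 pixel_size: float, step_ratio: float = 0.5) -> np.ndarray:
    """Exact transpose A^T of :func:`forward_project` (unfiltered smear)."""
    if s.values.shape[1] != geom.n_detectors:
        raise ValueError("detector count mismatch")
    step = step_ratio * pixel_size
    betas = np.deg2rad(s.view_angles)
    acc = np.zeros((image_size, image_size), dtype=np.float64)
    vals = s.values.astype(np.float64)
    for k, beta in enumerate(betas):
        rows, cols = _ray_samples(geom, beta, pixel_size, image_size, step)
        v = np.broadcast_to(vals[k][:, None] * step, rows.shape)
        acc += _bilinear_scatter(acc.shape, rows, cols, v)
    return acc


def subsample_views(s: Sinogram, n: int) -> Sinogram:
    """Keep every ``n_views / n``-th view (sparse-view acquisition)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if s.n_views % n != 0:
        raise ValueError(f"{n} does not divide the {s.n_views} stored views")
    stride = s.n_views // n
    return Sinogram(s.values[::stride].copy(), s.view_angles[::stride].copy(),
                    s.geometry)


def interpolate_views(s: Sinogram, n_target: int) -> Sinogram:
    """Bilinear view-axis upsampling, periodic over 360 degrees.

    The detector axis is never resampled; values at retained original
    angles reproduce the originals to floating-point tolerance.
    """
    n_src = s.n_views
    if n_target < n_src:
        raise ValueError("n_target must be >= current view count")
    if n_target == n_src:
        return Sinogram(s.values.copy(), s.view_angles.copy(), s.geometry)
    pos = np.arange(n_target) * (n_src / n_target)
    i0 = np.floor(pos).astype(np.intp)
    w = (pos - i0)[:, None]
    i1 = (i0 + 1) % n_src  # circular extension along the view axis
    vals = (1.0 - w) * s.values[i0] + w * s.values[i1]
    angles = np.arange(n_target) * (s.geometry.angular_span / n_target)
    return Sinogram(vals.astype(np.float32), angles, s.geometry)


def add_mixed_noise(s: Sinogram, p: NoiseParams) -> Sinogram:
    """Mixed Gaussian + Poisson corruption of a sinogram.

    The sinogram is mapped to transmittance t = exp(-s / MAX(s)), corrupted
    as detector counts N = Poisson(I0*t) + Normal(I0*m, var = I0*var), and
    restored by s' = -log(clamp(N, eps)/I0) * MAX(s).  Deterministic given
    the seed; noise vanishes in the I0 -> inf, var = 0 limit.
    """
    smax = float(s.values.max())
    if smax <= 0:
        raise ValueError("all-zero sinogram: MAX(s) = 0")
    rng = np.random.default_rng(p.seed)
    t = np.exp(-s.values.astype(np.float64) / smax)
    counts = rng.poisson(p.i0 * t).astype(np.float64)
    counts += rng.normal(p.i0 * p.gauss_mean, np.sqrt(p.i0 * p.gauss_var),
                         size=t.shape)
    t_hat = np.clip(counts, 1e-8, None) / p.i0
    out = (-np.log(t_hat) * smax).astype(np.float32)
    return Sinogram(out, s.view_angles.copy(), s.geometry)
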