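"""Synthetic piecewise-constant phantoms and paired sinogram datasets.

Phantoms stand in for clinical CT slices: a body-outline ellipse filled
with randomized internal ellipses plus at least one small high-contrast
insert, all with sharp boundaries so the high-frequency branches and the
edge loss have structure to act on.  Edges are anti-aliased by 4x
supersampled coverage averaging, which keeps the discrete projector's
line integrals close to the continuous ones.  The dataset builder writes
self-consistent HDF5 containers: reference image, full sinogram,
sparse-view subset, optional noisy sparse sinogram, view-interpolated
sinogram and FBP-of-interpolated baseline reconstruction per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import h5py
import numpy as np
import yaml

from .fbp import FBPConfig, fbp_reconstruct
from .geometry import (ImageGrid, NoiseParams, ScanGeometry, Sinogram,
                       add_mixed_noise, default_pixel_size, forward_project,
                       interpolate_views, subsample_views)


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 64
    n_ellipses: Tuple[int, int] = (3, 7)
    attenuation: Tuple[float, float] = (0.0, 0.04)  # per mm
    insert_contrast: Tuple[float, float] = (0.004, 0.012)
    seed: int = 0
    supersample: int = 4

    def __post_init__(self):
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")
        lo, hi = self.attenuation
        if not (0 <= lo < hi):
            raise ValueError("attenuation bounds must be ordered, non-negative")
        if self.n_ellipses[0] < 1 or self.n_ellipses[1] < self.n_ellipses[0]:
            raise ValueError("invalid n_ellipses range")


def _paint_ellipse(canvas, X, Y, cx, cy, a, b, theta, value):
    ct, st = np.cos(theta), np.sin(theta)
    xr = (X - cx) * ct + (Y - cy) * st
    yr = -(X - cx) * st + (Y - cy) * ct
    canvas[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] = value


def generate_phantom(spec: PhantomSpec, index: int,
                     pixel_size: float = 1.0) -> ImageGrid:
    """Deterministic phantom for (spec.seed, index), values in [0, mu_max]."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    n = spec.image_size * spec.supersample
    # coordinates normalized to [-1, 1] across the image width
    xs = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    X = np.broadcast_to(xs[None, :], (n, n))
    Y = np.broadcast_to(xs[:, None], (n, n))
    mu_lo, mu_hi = spec.attenuation
    canvas = np.zeros((n, n), dtype=np.float64)

    # body outline, kept inside the field-of-view circle
    body_a = rng.uniform(0.62, 0.82)
    body_b = rng.uniform(0.55, 0.80)
    body_t = rng.uniform(0, np.pi)
    body_mu = rng.uniform(0.4, 0.6) * mu_hi
    _paint_ellipse(canvas, X, Y, 0.0, 0.0, body_a, body_b, body_t, body_mu)

    n_int = rng.integers(spec.n_ellipses[0], spec.n_ellipses[1] + 1)
    for _ in range(n_int):
        cx, cy = rng.uniform(-0.4, 0.4, size=2)
        a = rng.uniform(0.06, 0.30)
        b = rng.uniform(0.06, 0.30)
        theta = rng.uniform(0, np.pi)
        mu = rng.uniform(0.2, 0.95) * mu_hi
        _paint_ellipse(canvas, X, Y, cx, cy, a, b, theta, mu)

    # small low-/high-contrast insert probing detail preservation
    cx, cy = rng.uniform(-0.3, 0.3, size=2)
    r_ins = rng.uniform(0.03, 0.06)
    contrast = rng.uniform(*spec.insert_contrast) * rng.choice([-1.0, 1.0])
    local = body_mu
    _paint_ellipse(canvas, X, Y, cx, cy, r_ins, r_ins, 0.0,
                   np.clip(local + contrast, mu_lo, mu_hi))

    # zero outside the body, clip into the attenuation range
    mask = np.zeros((n, n), dtype=bool)
    ct, st = np.cos(body_t), np.sin(body_t)
    xr = X * ct + Y * st
    yr = -X * st + Y * ct
    mask[(xr / body_a) ** 2 + (yr / body_b) ** 2 > 1.0] = True
    canvas[mask] = 0.0
    canvas = np.clip(canvas, mu_lo, mu_hi)

    s = spec.supersample
    img = canvas.reshape(spec.image_size, s, spec.image_size, s).mean(axis=(1, 3))
    return ImageGrid(img.astype(np.float32), pixel_size)


@dataclass(frozen=True)
class DatasetManifest:
    n_train: int = 96
    n_val: int = 16
    n_test: int = 16
    geometry: ScanGeometry = field(default_factory=lambda: ScanGeometry(
        n_views_full=128, n_detectors=180, detector_pitch=1.0))
    views: int = 32            # sparse view count
    noise: Optional[NoiseParams] = None
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split sizes must be non-negative")
        if self.views < 1 or self.geometry.n_views_full % self.views:
            raise ValueError("views must divide geometry.n_views_full")

    def to_dict(self):
        d = {
            "n_train": self.n_train, "n_val": self.n_val, "n_test": self.n_test,
            "views": self.views,
            "geometry": {k: getattr(self.geometry, k) for k in (
                "n_views_full", "angular_span", "source_to_detector",
                "source_to_isocenter", "n_detectors", "detector_pitch")},
            "phantom": {
                "image_size": self.phantom.image_size,
                "n_ellipses": list(self.phantom.n_ellipses),
                "attenuation": list(self.phantom.attenuation),
                "insert_contrast": list(self.phantom.insert_contrast),
                "seed": self.phantom.seed,
                "supersample": self.phantom.supersample,
            },
            "noise": None if self.noise is None else {
                "i0": self.noise.i0, "gauss_mean": self.noise.gauss_mean,
                "gauss_var": self.noise.gauss_var, "seed": self.noise.seed},
        }
        return d

    @classmethod
    def from_dict(cls, d) -> "DatasetManifest":
        ph = d.get("phantom", {})
        ph = PhantomSpec(
            image_size=ph.get("image_size", 64),
            n_ellipses=tuple(ph.get("n_ellipses", (3, 7))),
            attenuation=tuple(ph.get("attenuation", (0.0, 0.04))),
            insert_contrast=tuple(ph.get("insert_contrast", (0.004, 0.012))),
            seed=ph.get("seed", 0),
            supersample=ph.get("supersample", 4),
        )
        geom = ScanGeometry(**d["geometry"]) if "geometry" in d else \
            ScanGeometry(n_views_full=128, n_detectors=180)
        noise = None
        if d.get("noise"):
            noise = NoiseParams(**d["noise"])
        return cls(n_train=d.get("n_train", 96), n_val=d.get("n_val", 16),
                   n_test=d.get("n_test", 16), geometry=geom,
                   views=d.get("views", 32), noise=noise, phantom=ph)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


SPLITS = ("train", "val", "test")


def build_dataset(manifest: DatasetManifest, path) -> None:
    """Write the paired phantom/sinogram dataset to an HDF5 container."""
    geom = manifest.geometry
    spec = manifest.phantom
    px = default_pixel_size(geom, spec.image_size)
    fbp_cfg = FBPConfig(image_size=spec.image_size, pixel_size=px)
    sizes = {"train": manifest.n_train, "val": manifest.n_val,
             "test": manifest.n_test}
    n_full, n_det = geom.n_views_full, geom.n_detectors
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest.to_dict())
        fh.attrs["pixel_size"] = px
        index = 0
        for split in SPLITS:
            n = sizes[split]
            g = fh.create_group(split)
            ds_img = g.create_dataset(
                "image", (n, spec.image_size, spec.image_size), dtype="f4")
            ds_full = g.create_dataset(
                "sinogram_full", (n, n_full, n_det), dtype="f4")
            ds_sparse = g.create_dataset(
                "sinogram_sparse", (n, manifest.views, n_det), dtype="f4")
            ds_interp = g.create_dataset(
                "sinogram_interp", (n, n_full, n_det), dtype="f4")
            ds_base = g.create_dataset(
                "fbp_baseline", (n, spec.image_size, spec.image_size),
                dtype="f4")
            ds_noisy = None
            if manifest.noise is not None:
                ds_noisy = g.create_dataset(
                    "sinogram_noisy", (n, manifest.views, n_det), dtype="f4")
            g.attrs["first_index"] = index
            for i in range(n):
                img = generate_phantom(spec, index, pixel_size=px)
                full = forward_project(img, geom)
                sparse = subsample_views(full, manifest.views)
                source = sparse
                if manifest.noise is not None:
                    noise_i = NoiseParams(
                        i0=manifest.noise.i0,
                        gauss_mean=manifest.noise.gauss_mean,
                        gauss_var=manifest.noise.gauss_var,
                        seed=manifest.noise.seed + index)
                    source = add_mixed_noise(sparse, noise_i)
                    ds_noisy[i] = source.values
                interp = interpolate_views(source, n_full)
                base = fbp_reconstruct(interp, geom, fbp_cfg)
                ds_img[i] = img.pixels
                ds_full[i] = full.values
                ds_sparse[i] = sparse.values
                ds_interp[i] = interp.values
                ds_base[i] = base.pixels
                index += 1


class PhantomDataset:
    """In-memory view over a built HDF5 container."""

    def __init__(self, path):
        self.path = path
        with h5py.File(path, "r") as fh:
            self.manifest = DatasetManifest.from_dict(
                json.loads(fh.attrs["manifest"]))
            self.pixel_size = float(fh.attrs["pixel_size"])
            self._data = {}
            for split in SPLITS:
                g = fh[split]
                self._data[split] = {k: g[k][...] for k in g.keys()}

    def split(self, name):
        return self._data[name]

    def n(self, split) -> int:
        return self._data[split]["image"].shape[0]
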