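"""HDF5 containers, TIFF export and checkpoint serialization."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ImageGrid, NoiseParams, ScanGeometry, Sinogram

GEOMETRY_FIELDS = ("n_views_full", "angular_span", "source_to_detector",
                   "source_to_isocenter", "n_detectors", "detector_pitch")


def geometry_to_dict(geom: ScanGeometry) -> dict:
    return {k: getattr(geom, k) for k in GEOMETRY_FIELDS}


def geometry_from_dict(d: dict) -> ScanGeometry:
    return ScanGeometry(**{k: d[k] for k in GEOMETRY_FIELDS})


def write_sample(path, image: ImageGrid, geom: ScanGeometry,
                 sinogram_full: Sinogram = None,
                 sinogram_sparse: Sinogram = None,
                 sinogram_noisy: Sinogram = None,
                 noise: NoiseParams = None,
                 json_sidecar: bool = True) -> None:
    """Single-sample container: /image plus any available sinograms.

    Geometry (and noise parameters, if given) are stored as root
    attributes; a JSON sidecar mirrors the geometry for external tooling.
    """
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("image", data=image.pixels.astype(np.float32))
        fh.attrs["pixel_size"] = image.pixel_size
        for k, v in geometry_to_dict(geom).items():
            fh.attrs[f"geometry/{k}"] = v
        if noise is not None:
            fh.attrs["noise/i0"] = noise.i0
            fh.attrs["noise/gauss_mean"] = noise.gauss_mean
            fh.attrs["noise/gauss_var"] = noise.gauss_var
            fh.attrs["noise/seed"] = noise.seed
        for name, sino in (("sinogram_full", sinogram_full),
                           ("sinogram_sparse", sinogram_sparse),
                           ("sinogram_noisy", sinogram_noisy)):
            if sino is not None:
                ds = fh.create_dataset(name, data=sino.values.astype(np.float32))
                ds.attrs["view_angles"] = sino.view_angles
    if json_sidecar:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(
            {"geometry": geometry_to_dict(geom),
             "pixel_size": image.pixel_size}, indent=2))


def read_sample(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        geom = geometry_from_dict(
            {k: fh.attrs[f"geometry/{k}"] for k in GEOMETRY_FIELDS})
        out["geometry"] = geom
        out["image"] = ImageGrid(fh["image"][...],
                                 float(fh.attrs["pixel_size"]))
        for name in ("sinogram_full", "sinogram_sparse", "sinogram_noisy"):
            if name in fh:
                ds = fh[name]
                angles = np.asarray(ds.attrs["view_angles"])
                g = geom.with_views(ds.shape[0])
                out[name] = Sinogram(ds[...], angles, g)
    return out


def export_tiff(path, array) -> None:
    """32-bit float TIFF export of an image or sinogram for inspection."""
    if isinstance(array, ImageGrid):
        array = array.pixels
    elif isinstance(array, Sinogram):
        array = array.values
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
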