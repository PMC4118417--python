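"""Readers and writers: PNG/TIFF/NIfTI images, JSON transform schema."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .embedding import DiffusionMapImage, ImageGrid
from .registration import FFDTransform, RigidTransform, Transform

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(
    path: Union[str, Path],
    slice_axis: Optional[int] = None,
    slice_index: Optional[int] = None,
) -> ImageGrid:
    """Load a 2-D image (PNG/TIFF) or a slice of a NIfTI volume.

    For a 3-D NIfTI, `slice_axis`/`slice_index` pick the 2-D slice
    (default: middle slice along the last axis). Multichannel PNGs load
    as H x W x m.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        nii = nib.load(str(path))
        data = np.asanyarray(nii.dataobj).astype(float)
        zooms = nii.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) else 1.0
        if data.ndim == 3:
            axis = 2 if slice_axis is None else slice_axis
            idx = data.shape[axis] // 2 if slice_index is None else slice_index
            data = np.take(data, idx, axis=axis)
        elif data.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality: {data.ndim}")
        return ImageGrid(data, spacing=spacing)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(str(path)).astype(float)
    elif suffix in (".png", ".jpg", ".jpeg", ".bmp"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(str(path))).astype(float)
    else:
        raise ValueError(f"unsupported image format: '{suffix or path.name}'")
    if data.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality: {data.ndim}")
    return ImageGrid(data)


def write_image(
    img: Union[ImageGrid, DiffusionMapImage], path: Union[str, Path]
) -> None:
    """Write as float32 TIFF or NIfTI; coordinates are not requantized."""
    path = Path(path)
    data = img.data if isinstance(img, ImageGrid) else img.coords
    data = np.squeeze(np.asarray(data, dtype=np.float32))
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), data)
    else:
        raise ValueError(
            f"unsupported output format '{path.suffix}'; use .tif or .nii[.gz]"
        )


def transform_to_dict(transform: Transform) -> dict:
    if isinstance(transform, RigidTransform):
        return {
            "model": "rigid",
            "theta": transform.theta,
            "t": list(transform.t),
            "center": list(transform.center),
        }
    if isinstance(transform, FFDTransform):
        return {
            "model": "ffd",
            "spacing": transform.spacing,
            "grid_shape": list(transform.ctrl.shape),
            "image_shape": list(transform.shape),
            "ctrl": transform.ctrl.ravel().tolist(),
        }
    raise TypeError(f"not a transform: {type(transform)}")


def transform_from_dict(d: dict) -> Transform:
    model = d.get("model")
    if model == "rigid":
        return RigidTransform(
            float(d["theta"]), tuple(d["t"]), tuple(d.get("center", (0.0, 0.0)))
        )
    if model == "ffd":
        ctrl = np.asarray(d["ctrl"], dtype=float).reshape(d["grid_shape"])
        return FFDTransform(ctrl, float(d["spacing"]), tuple(d["image_shape"]))
    raise ValueError(f"unknown transform model: {model!r}")


def save_transform(transform: Transform, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(transform), indent=2))


def load_transform(path: Union[str, Path]) -> Transform:
    return transform_from_dict(json.loads(Path(path).read_text()))


def save_field(field: np.ndarray, path: Union[str, Path]) -> None:
    """Dense H x W x 2 displacement field as a 2-channel NIfTI/TIFF."""
    write_image(DiffusionMapImage(np.asarray(field)), path)
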