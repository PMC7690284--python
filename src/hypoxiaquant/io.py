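"""File I/O for volumes, images, masks, tables and ground-truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .errors import ValidationError
from .pet import SUVVolume


def write_nifti(path: str | Path, values: np.ndarray, spacing_mm) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))


def read_nifti_volume(path: str | Path) -> SUVVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SUVVolume(np.asarray(img.get_fdata(), dtype=float), spacing)


def read_nifti_mask(path: str | Path, like: SUVVolume | None = None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata()) > 0.5
    if like is not None and mask.shape != like.values.shape:
        raise ValidationError(
            f"mask grid {mask.shape} is not aligned with volume grid {like.values.shape}"
        )
    return mask


def write_rgb_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint8))


def read_rgb_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(str(path))
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValidationError(f"{path.name}: expected an RGB image")
    return img[..., :3]


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    mask = np.asarray(iio.imread(Path(path)))
    if mask.ndim == 3:
        mask = mask[..., 0]
    return mask > 127


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
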