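"""Readers and writers for images, label maps, seeds and configs.

Supported image formats are 8-bit grayscale PNG and NIfTI-1
(``.nii`` / ``.nii.gz``).  Label maps are always stored as integers —
never rescaled floats — so that cost and RMS arithmetic on round-tripped
maps stays exact.  Seed sets and run configurations travel as JSON,
metrics as JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import FormatError
from .phantom import (CLASS_NAMES, PhantomSpec, ReferenceSegmentation,
                      TISSUE_CLASSES)

PathLike = Union[str, Path]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path: PathLike, slice_index: Optional[int] = None) -> np.ndarray:
    """Read a scalar image as a float64 array.

    PNG inputs must be single-channel grayscale; color PNGs are rejected
    rather than silently converted.  NIfTI volumes with three dimensions
    are reduced to the axial slice ``slice_index`` (required when the
    volume has more than one slice).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is not None:
                data = data[:, :, int(slice_index)]
            else:
                raise FormatError(
                    f"{path} is a 3-D volume of shape {data.shape}; "
                    "pass slice_index to select an axial slice"
                )
        if data.ndim != 2:
            raise FormatError(f"{path}: expected 2-D data, got shape {data.shape}")
        return np.asarray(data, dtype=np.float64)
    try:
        data = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if data.ndim == 3:
        raise FormatError(
            f"{path} has {data.shape[2]} channels; grayscale input required"
        )
    return np.asarray(data, dtype=np.float64)


def write_image(image: np.ndarray, path: PathLike) -> None:
    """Write a scalar image: float32 NIfTI, or PNG quantized to uint8."""
    path = Path(path)
    arr = np.asarray(image)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)),
                 str(path))
        return
    if path.suffix.lower() != ".png":
        raise FormatError(f"unsupported image format: {path}")
    iio.imwrite(path, np.clip(np.rint(arr), 0, 255).astype(np.uint8))


def read_label_map(path: PathLike) -> np.ndarray:
    """Read an integer label map from PNG or NIfTI."""
    labels = read_image(path)
    if not np.all(labels == np.rint(labels)):
        raise FormatError(f"{path} does not contain integer labels")
    return labels.astype(np.int32)


def write_label_map(labels: np.ndarray, path: PathLike) -> None:
    """Write an integer label map losslessly.

    NIfTI uses int16; PNG stores the raw label values as 8-bit gray
    (label 0 renders as black), so a write→read round-trip returns the
    identical array.
    """
    path = Path(path)
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError("label maps must have an integer dtype")
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.astype(np.int16), affine=np.eye(4)),
                 str(path))
        return
    if path.suffix.lower() != ".png":
        raise FormatError(f"unsupported label-map format: {path}")
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError("PNG label maps support labels 0..255 only")
    iio.imwrite(path, arr.astype(np.uint8))


def read_mask(path: PathLike) -> np.ndarray:
    """Read a binary mask: any non-zero pixel counts as foreground."""
    return read_label_map(path) != 0


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    """Write a binary mask (0 background, 255 foreground for PNG)."""
    path = Path(path)
    arr = np.asarray(mask, dtype=bool)
    if _is_nifti(path):
        write_label_map(arr.astype(np.int16), path)
    else:
        write_label_map(arr.astype(np.int32) * 255, path)


def read_reference(paths: Dict[int, PathLike]) -> ReferenceSegmentation:
    """Assemble a reference segmentation from per-class mask files."""
    ref = ReferenceSegmentation(masks={c: read_mask(p) for c, p in paths.items()})
    ref.validate()
    return ref


def write_seeds(seeds, path: PathLike) -> None:
    Path(path).write_text(json.dumps(seeds.to_dict(), indent=2, sort_keys=True)
                          + "\n")


def read_seeds(path: PathLike):
    from .ga import SeedSet  # local import to avoid a cycle

    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read seeds file {path}: {exc}") from exc
    return SeedSet.from_dict(d)


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read JSON file {path}: {exc}") from exc


def write_history_csv(history, path: PathLike) -> None:
    """Per-generation best-cost history as a two-column CSV."""
    lines = ["generation,best_cost"]
    lines += [f"{i},{cost}" for i, cost in enumerate(history)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_phantom(out_dir: PathLike, image: np.ndarray,
                  ref: ReferenceSegmentation, spec: PhantomSpec,
                  fmt: str = "png") -> Dict[str, Path]:
    """Write a phantom image, its per-class masks and its spec.

    Returns a name -> path mapping of everything written: the image,
    one mask per tissue class, and the spec JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".png" if fmt == "png" else ".nii.gz"
    written: Dict[str, Path] = {}
    img_path = out_dir / f"image{ext}"
    write_image(image, img_path)
    written["image"] = img_path
    for c in TISSUE_CLASSES:
        p = out_dir / f"mask_{CLASS_NAMES[c]}{ext}"
        write_mask(ref.masks[c], p)
        written[f"mask_{CLASS_NAMES[c]}"] = p
    spec_path = out_dir / "phantom_spec.json"
    write_json(spec.to_dict(), spec_path)
    written["spec"] = spec_path
    return written
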