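"""Reading and writing images, masks and run configuration.

NIfTI (.nii/.nii.gz) files go through nibabel with their affine and header
preserved for round-tripping; PNGs are loaded as grayscale with 8- and
16-bit depths preserved exactly.  Masks are written as {0, 1} in the
source bit depth, NIfTI masks inheriting the source affine.  Pixel
indexing is 0-based row-major throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

__all__ = ["ImageMeta", "RunConfig", "read_image", "write_image",
           "write_mask"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PNG_SUFFIXES = (".png",)


@dataclass
class ImageMeta:
    """Geometry/provenance needed to write results next to their source."""

    format: str                      # 'nifti' or 'png'
    path: str | None = None
    affine: np.ndarray | None = None
    header: object = None
    dtype: str | None = None


def _fmt_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_PNG_SUFFIXES):
        return "png"
    raise IOError(f"unsupported image format: {path} "
                  "(expected .nii, .nii.gz or .png)")


def read_image(path):
    """Read a NIfTI or grayscale PNG image -> (float array, ImageMeta)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    fmt = _fmt_of(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        meta = ImageMeta(format="nifti", path=str(path), affine=img.affine,
                         header=img.header.copy(),
                         dtype=str(img.get_data_dtype()))
        return data, meta
    pil = Image.open(path)
    if pil.mode not in ("L", "I", "I;16", "F"):
        pil = pil.convert("L")
    arr = np.asarray(pil)
    return arr.astype(float), ImageMeta(format="png", path=str(path),
                                        dtype=str(arr.dtype))


def write_image(path, data, meta: ImageMeta | None = None) -> None:
    """Write an array as NIfTI or PNG, preserving source geometry."""
    path = Path(path)
    fmt = _fmt_of(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = meta.affine if meta is not None and meta.affine is not None \
            else np.eye(4)
        img = nib.Nifti1Image(np.asarray(data), affine)
        nib.save(img, str(path))
        return
    arr = np.asarray(data)
    if meta is not None and meta.dtype == "uint16":
        Image.fromarray(arr.astype(np.uint16)).save(path)
    else:
        Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8),
                        mode="L").save(path)


def write_mask(path, mask, meta: ImageMeta | None = None) -> None:
    """Write a binary mask as {0, 1} in the source bit depth."""
    mask01 = np.asarray(mask).astype(bool).astype(np.uint8)
    path = Path(path)
    if _fmt_of(path) == "nifti":
        affine = meta.affine if meta is not None and meta.affine is not None \
            else np.eye(4)
        nib.save(nib.Nifti1Image(mask01, affine), str(path))
    else:
        write_image(path, mask01, meta)


@dataclass
class RunConfig:
    """Merged pipeline configuration, YAML round-trippable.

    Unknown keys in a YAML file are rejected so typos never silently fall
    back to defaults.
    """

    seed: int = 0
    verbosity: int = 1
    input_path: str | None = None
    output_path: str | None = None
    em: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)
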