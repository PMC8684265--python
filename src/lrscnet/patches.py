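"""Image loading, manifests, and sliding-window patch extraction.

Every downstream stage of the classifier consumes m-by-m grayscale
patches cut from lesion images on a regular grid.  This module owns the
image container (:class:`GrayImage`), the patch container
(:class:`Patch`), the CSV manifest format and the extraction grid.

Conventions
-----------
* Intensities live in ``[0, 1]``; integer rasters are divided by their
  format's maximum value on load.
* Patch origins are 0-based ``(row, col)`` of the top-left corner.
* Extraction order is row-major over the origin grid and deterministic.
* Patches carry raw intensities: the reference-learning stage averages
  patches directly, so no per-patch standardization is applied here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .exceptions import DecodeError, SchemaError, ValidationError

#: The two lesion classes. Benign is the positive class throughout.
LABELS = ("benign", "malignant")

# ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def normalize_label(raw: str) -> str:
    """Map a label string to ``'benign'`` or ``'malignant'`` (case-insensitive)."""
    label = str(raw).strip().lower()
    if label not in LABELS:
        raise ValidationError(
            f"unknown class label {raw!r}; expected one of {LABELS}"
        )
    return label


@dataclass
class GrayImage:
    """A single-channel lesion image with optional ROI mask and class label.

    Attributes
    ----------
    pixels : (H, W) float array with values in [0, 1].
    image_id : opaque identifier (usually the file stem).
    label : 'benign' | 'malignant' | None.  Required for training images.
    roi : optional (H, W) boolean lesion mask (True = inside the lesion).
    """

    pixels: np.ndarray
    image_id: str
    label: Optional[str] = None
    roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"image {self.image_id!r}: pixels must be 2-D, got shape "
                f"{self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(
                f"image {self.image_id!r}: intensities must lie in [0, 1], "
                f"found range [{lo:.4g}, {hi:.4g}]"
            )
        if self.label is not None:
            self.label = normalize_label(self.label)
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != self.pixels.shape:
                raise ValidationError(
                    f"image {self.image_id!r}: ROI mask shape {self.roi.shape} "
                    f"does not match image shape {self.pixels.shape}"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Patch:
    """An m-by-m block of a parent image.

    ``values`` are raw intensities in [0, 1]; ``origin`` is the 0-based
    (row, col) of the top-left corner in the parent image; ``label`` is
    inherited from the parent (None for unlabeled prediction-time images).
    """

    values: np.ndarray
    origin: tuple[int, int]
    image_id: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(
                f"patch values must be square 2-D, got shape {self.values.shape}"
            )

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass
class PatchConfig:
    """Sliding-window settings shared by training and inference.

    m : patch side in pixels (window is m x m).
    stride : grid step; defaults to m // 2 (50% overlap).
    roi_min_frac : keep a patch only if at least this fraction of its
        pixels falls inside the ROI mask (ignored when no mask).
    """

    m: int = 16
    stride: Optional[int] = None
    roi_min_frac: float = 0.5

    def resolved_stride(self) -> int:
        return self.stride if self.stride is not None else max(1, self.m // 2)


@dataclass
class ManifestRow:
    image: Path
    label: str
    mask: Optional[Path] = None
    split: Optional[str] = None


def _to_unit_interval(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    out = arr.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def load_image(
    path: Path | str,
    mask_path: Optional[Path | str] = None,
    label: Optional[str] = None,
    image_id: Optional[str] = None,
) -> GrayImage:
    """Read a PNG/TIFF raster as a [0, 1] grayscale image with optional mask.

    RGB(A) inputs are collapsed to luminance; integer intensities are
    divided by the dtype maximum.  Masks are binarized at > 0 and must
    match the image shape.
    """
    path = Path(path)
    try:
        raw = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises various types
        raise DecodeError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3:
        rgb = _to_unit_interval(raw[..., :3])
        pixels = rgb @ _LUMA
    elif raw.ndim == 2:
        pixels = _to_unit_interval(raw)
    else:
        raise DecodeError(f"{path}: expected 2-D or RGB image, got shape {raw.shape}")

    roi = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        try:
            mraw = np.asarray(iio.imread(mask_path))
        except Exception as exc:
            raise DecodeError(f"cannot read mask {mask_path}: {exc}") from exc
        if mraw.ndim == 3:
            mraw = mraw[..., 0]
        if mraw.shape != pixels.shape:
            raise ValidationError(
                f"mask {mask_path} shape {mraw.shape} does not match image "
                f"{path} shape {pixels.shape}"
            )
        roi = mraw > 0

    return GrayImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        image_id=image_id if image_id is not None else path.stem,
        label=label,
        roi=roi,
    )


def read_manifest(path: Path | str) -> list[ManifestRow]:
    """Parse a dataset manifest CSV.

    Required columns: ``image``, ``label``; optional: ``mask`` (may be
    empty) and ``split`` (``train``/``test``).  Relative paths resolve
    against the manifest's directory.  Rows are returned in file order.
    """
    path = Path(path)
    base = path.parent
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = {"image", "label"} - set(fields)
        if missing:
            raise SchemaError(
                f"manifest {path} is missing required column(s) {sorted(missing)}; "
                f"found {fields}"
            )
        for lineno, rec in enumerate(reader, start=2):
            try:
                label = normalize_label(rec["label"])
            except ValidationError as exc:
                raise ValidationError(f"manifest {path} row {lineno}: {exc}") from exc
            mask = rec.get("mask") or None
            split = (rec.get("split") or "").strip().lower() or None
            rows.append(
                ManifestRow(
                    image=base / rec["image"],
                    label=label,
                    mask=(base / mask) if mask else None,
                    split=split,
                )
            )
    return rows


def extract_patches(
    image: GrayImage,
    m: int = 16,
    stride: Optional[int] = None,
    roi_min_frac: float = 0.5,
) -> list[Patch]:
    """Cut the sliding-window grid of m-by-m patches from an image.

    Origins are ``(i * stride, j * stride)`` for every in-bounds grid
    point, visited row-major.  When the image carries an ROI mask, only
    patches with at least ``roi_min_frac`` of their pixels inside the
    mask are kept.  An empty result is legal (the caller decides whether
    that is an error).
    """
    if stride is None:
        stride = max(1, m // 2)
    if m < 1 or stride < 1:
        raise ValidationError(f"patch side and stride must be >= 1, got m={m}, stride={stride}")
    H, W = image.pixels.shape
    if m > H or m > W:
        raise ValidationError(
            f"patch side m={m} exceeds image {image.image_id!r} bounds {H}x{W}"
        )
    patches: list[Patch] = []
    for i in range(0, H - m + 1, stride):
        for j in range(0, W - m + 1, stride):
            if image.roi is not None:
                frac = image.roi[i : i + m, j : j + m].mean()
                if frac < roi_min_frac:
                    continue
            patches.append(
                Patch(
                    values=image.pixels[i : i + m, j : j + m].copy(),
                    origin=(i, j),
                    image_id=image.image_id,
                    label=image.label,
                )
            )
    return patches


def extract_patches_cfg(image: GrayImage, cfg: PatchConfig) -> list[Patch]:
    """`extract_patches` driven by a :class:`PatchConfig`."""
    return extract_patches(
        image, m=cfg.m, stride=cfg.resolved_stride(), roi_min_frac=cfg.roi_min_frac
    )


def stack_values(patches: Sequence[Patch]) -> np.ndarray:
    """Stack patch intensity grids into an (n, m, m) array."""
    if len(patches) == 0:
        raise ValidationError("cannot stack an empty patch list")
    return np.stack([p.values for p in patches])
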