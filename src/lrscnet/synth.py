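"""Seeded two-class synthetic breast-ultrasound phantoms.

Generates speckled lesion images so the whole
cluster/train/encode/classify loop runs with no external data.  The
texture model is fully developed speckle: the squared magnitude of a
complex Gaussian field smoothed by an isotropic Gaussian kernel whose
sigma is the class's *correlation length* (the speckle grain size),
log-compressed as a B-mode display would.  The two classes differ in
texture statistics, not mean brightness: benign lesions get long
correlation lengths (smooth, coarse-grained speckle), malignant ones
short (fine, gritty speckle), mirroring the clinical observation that
benign lesion texture tends to be smoother.  A hypoechoic lesion is
carved at the image center: its boundary is a radius-perturbed closed
curve (Fourier perturbation of a circle, larger for malignant to mimic
margin irregularity) and its interior intensity is scaled down by the
lesion contrast.  The lesion mask is emitted as the ROI.

Everything is deterministic given ``(spec.seed, class, index)``: each
image draws from its own ``SeedSequence``, so regenerating any single
image — or the whole dataset — reproduces it bit for bit.  (Exact byte
equality across platforms rests on IEEE-754 double arithmetic and the
platform's libm transcendental rounding; identical platforms always
agree.)
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .patches import GrayImage, LABELS

__all__ = ["SynthSpec", "generate_image", "generate_images", "generate_dataset"]

_CLASS_CODE = {"benign": 1, "malignant": 2}


@dataclass
class SynthSpec:
    """Study conditions for the synthetic two-class phantom.

    image_side : square image side in pixels.
    n_per_class : images generated per class.
    benign_correlation_length / malignant_correlation_length : Gaussian
        smoothing sigma (pixels) of the underlying complex field; the
        speckle grain size.  Benign > malignant (smooth vs coarse).
    lesion_contrast : multiplicative intensity factor of the hypoechoic
        lesion interior (0 = anechoic, 1 = no contrast).
    benign_boundary_irregularity / malignant_boundary_irregularity :
        relative amplitude of the Fourier radius perturbation
        (0 = perfect circle; malignant margins are more jagged).
    noise_floor : sigma of additive Gaussian sensor noise after
        compression.
    mean_shift : optional brightness offset added to benign lesions —
        an "easy mode" for fast smoke tests; 0 (off) by default so the
        classifier cannot succeed by a brightness threshold.
    train_fraction : stratified train share written to the manifest.
    seed : master seed; every image derives its own stream from it.
    """

    image_side: int = 128
    n_per_class: int = 100
    benign_correlation_length: float = 5.0
    malignant_correlation_length: float = 1.5
    lesion_contrast: float = 0.5
    benign_boundary_irregularity: float = 0.1
    malignant_boundary_irregularity: float = 0.4
    noise_floor: float = 0.02
    mean_shift: float = 0.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 32:
            raise ValidationError("image_side must be >= 32 (at least 4 patch sides)")
        if self.benign_correlation_length <= 0 or self.malignant_correlation_length <= 0:
            raise ValidationError("correlation lengths must be positive")
        if not (0.0 <= self.lesion_contrast <= 1.0):
            raise ValidationError("lesion_contrast must lie in [0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie in (0, 1)")
        if (
            self.benign_correlation_length == self.malignant_correlation_length
            and self.benign_boundary_irregularity == self.malignant_boundary_irregularity
            and self.mean_shift == 0.0
        ):
            raise ValidationError(
                "the two classes must differ in at least one parameter"
            )

    def class_params(self, label: str) -> tuple[float, float]:
        """(correlation_length, boundary_irregularity) for a class."""
        if label == "benign":
            return self.benign_correlation_length, self.benign_boundary_irregularity
        return self.malignant_correlation_length, self.malignant_boundary_irregularity


def _speckle(rng: np.random.Generator, side: int, corr_len: float) -> np.ndarray:
    """Fully developed speckle: |smoothed complex Gaussian|^2, log-compressed."""
    re = gaussian_filter(rng.standard_normal((side, side)), corr_len, mode="wrap")
    im = gaussian_filter(rng.standard_normal((side, side)), corr_len, mode="wrap")
    intensity = re * re + im * im
    intensity /= intensity.mean()
    return np.log1p(5.0 * intensity)  # B-mode-like dynamic range compression


def _lesion_mask(
    rng: np.random.Generator, side: int, irregularity: float
) -> np.ndarray:
    """Radius-perturbed closed-curve lesion mask centered in the image."""
    center = (side - 1) / 2.0
    base_radius = 0.30 * side
    rows, cols = np.mgrid[0:side, 0:side]
    dy, dx = rows - center, cols - center
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    perturb = np.zeros_like(theta)
    if irregularity > 0:
        for h in range(2, 7):  # low harmonics: lobulated-to-jagged margins
            a, b = rng.standard_normal(2) / h
            perturb += a * np.cos(h * theta) + b * np.sin(h * theta)
        perturb *= irregularity
    boundary = base_radius * np.clip(1.0 + perturb, 0.3, 1.7)
    return radius <= boundary


def generate_image(label: str, spec: SynthSpec, index: int) -> GrayImage:
    """One deterministic phantom: speckle background, hypoechoic lesion
    with a class-dependent margin, and the lesion mask as ROI."""
    if label not in LABELS:
        raise ValidationError(f"unknown class {label!r}; expected one of {LABELS}")
    corr_len, irregularity = spec.class_params(label)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), _CLASS_CODE[label], int(index)])
    )
    img = _speckle(rng, spec.image_side, corr_len)
    mask = _lesion_mask(rng, spec.image_side, irregularity)
    img = np.where(mask, img * spec.lesion_contrast, img)
    if spec.mean_shift and label == "benign":
        img = np.where(mask, img + spec.mean_shift, img)
    if spec.noise_floor > 0:
        img = img + spec.noise_floor * rng.standard_normal(img.shape)
    lo, hi = img.min(), img.max()
    pixels = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return GrayImage(
        pixels=pixels,
        image_id=f"{label}_{index:04d}",
        label=label,
        roi=mask,
    )


def generate_images(spec: SynthSpec) -> list[GrayImage]:
    """All n_per_class images of both classes, in (benign..., malignant...)
    order, entirely in memory."""
    return [
        generate_image(label, spec, i)
        for label in LABELS
        for i in range(spec.n_per_class)
    ]


def stratified_split(
    labels: list[str], train_fraction: float, seed: int
) -> list[str]:
    """Per-class seeded shuffle into 'train'/'test' tags (order preserved).

    The train count per class is round(fraction * n), clamped so both
    sides stay non-empty; exact 80/20 when n is a multiple of 5."""
    out = ["test"] * len(labels)
    rng = np.random.default_rng(seed)
    for cls in LABELS:
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        if not idx:
            continue
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        chosen = rng.permutation(len(idx))[:n_train]
        for c in chosen:
            out[idx[c]] = "train"
    return out


def generate_dataset(spec: SynthSpec, out_dir: Path | str) -> Path:
    """Write images + masks as PNG plus a manifest CSV with a stratified
    train/test split column.  Returns the manifest path; regenerating
    with the same spec reproduces identical bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    labels = []
    for label in LABELS:
        for i in range(spec.n_per_class):
            img = generate_image(label, spec, i)
            img_name = f"{img.image_id}.png"
            mask_name = f"{img.image_id}_mask.png"
            iio.imwrite(out_dir / img_name, (img.pixels * 255).round().astype(np.uint8))
            iio.imwrite(out_dir / mask_name, (img.roi.astype(np.uint8) * 255))
            rows.append([img_name, label, mask_name])
            labels.append(label)
    split = stratified_split(labels, spec.train_fraction, spec.seed)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "label", "mask", "split"])
        for row, sp in zip(rows, split):
            writer.writerow(row + [sp])
    return manifest
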