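"""Binary semantic codes and the training-free self-matching classifier.

Each patch's similarity vector F_ls (benign references first, then
malignant) is collapsed to one semantic bit: p is the mean similarity
over the *benign block* and the bit is B = 1 when p >= 0.5 (a bit of 1
says "this local patch looks benign").  The per-image code is the
ordered bit string over its patches.  Classification needs no training:
the self-matching layer averages the bits, l = mean(B), and calls the
image benign exactly when l > 0.5.  Note the asymmetric boundaries —
p = 0.5 yields bit 1, but l = 0.5 yields malignant (the strict
inequality is the conservative choice for a cancer screen).

The real-valued per-patch p's are retained alongside the bits; their
mean is the continuous benign-likelihood score used for ROC analysis
(the hard decision always comes from the bits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .encoder import BackboneParams, SimilarityHeadParams, local_similarity_matrix
from .exceptions import ValidationError
from .patches import GrayImage, PatchConfig, extract_patches_cfg, stack_values
from .references import LocalReferenceSet

__all__ = [
    "SemanticCode",
    "Decision",
    "semantic_bit",
    "image_semantic_code",
    "self_match",
    "continuous_score",
]

#: signature: (patch_values (n, m, m), refs) -> (n, k+r) similarity matrix.
SimilarityFn = Callable[[np.ndarray, LocalReferenceSet], np.ndarray]


@dataclass
class SemanticCode:
    """Per-image binary code: one bit per patch, in extraction order.

    ``bits[j]`` in {0, 1}; ``per_patch_p[j]`` is the real-valued benign
    similarity the bit was thresholded from; ``n`` is the code length
    (= the image's patch count).
    """

    bits: np.ndarray
    per_patch_p: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        self.per_patch_p = np.asarray(self.per_patch_p, dtype=np.float64)
        if self.bits.ndim != 1 or self.bits.shape != self.per_patch_p.shape:
            raise ValidationError(
                f"bits {self.bits.shape} and per_patch_p {self.per_patch_p.shape} "
                "must be equal-length 1-D vectors"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("semantic bits must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.bits)

    def bit_string(self) -> str:
        return "".join(str(int(b)) for b in self.bits)


@dataclass
class Decision:
    """Self-matching output: l = mean(bits) and the thresholded label."""

    l: float
    label: str


def semantic_bit(f_ls: np.ndarray, k_benign: int) -> tuple[float, int]:
    """Collapse one patch's similarity vector to (p, B).

    ``f_ls`` lists similarities with the ``k_benign`` benign references
    first.  p is the mean over that benign block; B = 1 iff p >= 0.5.
    """
    f_ls = np.asarray(f_ls, dtype=np.float64)
    if k_benign < 1:
        raise ValidationError("the benign block must contain at least one reference")
    if f_ls.ndim != 1 or len(f_ls) < k_benign:
        raise ValidationError(
            f"similarity vector of length {f_ls.shape} cannot hold a benign "
            f"block of {k_benign}"
        )
    if f_ls.min() < -1e-9 or f_ls.max() > 1 + 1e-9:
        raise ValidationError("similarities must lie in [0, 1]")
    p = float(f_ls[:k_benign].mean())
    return p, int(p >= 0.5)


def image_semantic_code(
    image: GrayImage,
    refs: LocalReferenceSet,
    bb: Optional[BackboneParams],
    head: Optional[SimilarityHeadParams],
    patch_config: Optional[PatchConfig] = None,
    similarity_fn: Optional[SimilarityFn] = None,
) -> SemanticCode:
    """Encode an image: extract patches, compute each patch's F_ls, and
    threshold the benign-block mean into one bit per patch.

    ``similarity_fn`` replaces the learned encoder when given (used for
    oracle-style analyses); otherwise ``bb`` and ``head`` are required.
    """
    cfg = patch_config or PatchConfig()
    patches = extract_patches_cfg(image, cfg)
    if not patches:
        raise ValidationError(
            f"image {image.image_id!r} yields no patches under m={cfg.m}, "
            f"stride={cfg.resolved_stride()}, roi_min_frac={cfg.roi_min_frac}; "
            "relax roi_min_frac or reduce the stride"
        )
    values = stack_values(patches)
    if similarity_fn is not None:
        sim = np.asarray(similarity_fn(values, refs), dtype=np.float64)
    else:
        if bb is None or head is None:
            raise ValidationError("backbone and head are required without a similarity_fn")
        sim = local_similarity_matrix(values, refs, bb, head)
    p = sim[:, : refs.k].mean(axis=1)
    return SemanticCode(bits=(p >= 0.5).astype(np.int8), per_patch_p=p, image_id=image.image_id)


def self_match(code: SemanticCode) -> Decision:
    """Training-free classification: l = mean of bits; benign iff l > 0.5.

    l exactly 0.5 is malignant (the benign rule is a strict inequality).
    Permutation-invariant in the bits; no stored state.
    """
    if code.n < 1:
        raise ValidationError("cannot classify an empty semantic code")
    l = float(code.bits.mean())
    return Decision(l=l, label="benign" if l > 0.5 else "malignant")


def continuous_score(
    image: GrayImage,
    refs: LocalReferenceSet,
    bb: Optional[BackboneParams],
    head: Optional[SimilarityHeadParams],
    patch_config: Optional[PatchConfig] = None,
    similarity_fn: Optional[SimilarityFn] = None,
) -> float:
    """Mean of the per-patch p values before binarization — a finer-grained
    benign-likelihood in [0, 1] used only for ROC analysis."""
    code = image_semantic_code(image, refs, bb, head, patch_config, similarity_fn)
    return float(code.per_patch_p.mean())
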