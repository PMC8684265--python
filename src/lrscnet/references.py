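"""Learning class-labeled local references by class-guided clustering.

A *local reference* is a prototype m-by-m patch representing a common
local tumor structure, tagged with the class (benign or malignant) of
the patches it summarizes.  References are learned by minimizing a
class-guided distance objective: the indicator weighting zeroes every
cross-class term, so the problem decomposes into two independent
Lloyd-style k-means runs — one over benign patches (k centroids mu_i),
one over malignant patches (r centroids theta_i).  Both run under one
operation so the class tag of each reference is intrinsic.

Numerical policy
----------------
* Distances are squared Euclidean on flattened raw intensities; no
  whitening or per-patch standardization (centroids are plain means of
  patches, so they stay inside [0, 1]).
* Nearest-centroid ties break to the lowest reference index.
* Convergence is declared when the assignment is unchanged between
  consecutive iterations (centroid equality is fragile in floating
  point); ``max_iter`` caps the loop.
* An emptied cluster is repaired by re-seeding it with the in-class
  patch farthest from its nearest current reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .patches import LABELS, Patch

__all__ = [
    "LocalReferenceSet",
    "ClusterAssignment",
    "init_references",
    "assign_patches",
    "update_references",
    "objective_value",
    "learn_local_references",
]


@dataclass
class LocalReferenceSet:
    """The learned codebook: k benign and r malignant reference patches.

    ``benign`` has shape (k, m, m) and ``malignant`` shape (r, m, m);
    both are ordered, and downstream similarity vectors use the ordering
    [benign_1..benign_k, malignant_1..malignant_r].  ``meta`` records the
    learning run (seed, iterations, final objective, objective trace).
    """

    benign: np.ndarray
    malignant: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.benign = np.asarray(self.benign, dtype=np.float64)
        self.malignant = np.asarray(self.malignant, dtype=np.float64)
        for name, arr in (("benign", self.benign), ("malignant", self.malignant)):
            if arr.ndim != 3 or arr.shape[0] < 1:
                raise ValidationError(
                    f"{name} references must be a non-empty (count, m, m) array, "
                    f"got shape {arr.shape}"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} references contain non-finite values")
        if self.benign.shape[1:] != self.malignant.shape[1:]:
            raise ValidationError(
                f"benign side {self.benign.shape[1:]} != malignant side "
                f"{self.malignant.shape[1:]}"
            )

    @property
    def k(self) -> int:
        return self.benign.shape[0]

    @property
    def r(self) -> int:
        return self.malignant.shape[0]

    @property
    def m(self) -> int:
        return self.benign.shape[1]

    def all_references(self) -> np.ndarray:
        """(k + r, m, m) stack, benign block first (the F_ls ordering)."""
        return np.concatenate([self.benign, self.malignant], axis=0)

    def save(self, directory: Path | str, prefix: str = "references") -> Path:
        """Write arrays (.npz) plus a JSON sidecar; returns the sidecar path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / f"{prefix}.npz", benign=self.benign, malignant=self.malignant)
        sidecar = directory / f"{prefix}.json"
        payload = {"m": self.m, "k": self.k, "r": self.r}
        payload.update(
            {key: self.meta[key] for key in ("seed", "iterations", "final_objective") if key in self.meta}
        )
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return sidecar

    @classmethod
    def load(cls, directory: Path | str, prefix: str = "references") -> "LocalReferenceSet":
        directory = Path(directory)
        with np.load(directory / f"{prefix}.npz") as data:
            benign, malignant = data["benign"], data["malignant"]
        sidecar = directory / f"{prefix}.json"
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(benign=benign, malignant=malignant, meta=meta)


@dataclass
class ClusterAssignment:
    """Partition of each class's patches over that class's references.

    ``benign_sets[i]`` holds indices (into the *benign* patch subset)
    assigned to benign reference i; likewise ``malignant_sets``.  Classes
    never mix: a benign patch can only join a benign reference's set.
    """

    benign_sets: list[np.ndarray]
    malignant_sets: list[np.ndarray]

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat per-patch cluster labels (benign_labels, malignant_labels)."""
        return (
            _sets_to_labels(self.benign_sets),
            _sets_to_labels(self.malignant_sets),
        )


def _sets_to_labels(sets: list[np.ndarray]) -> np.ndarray:
    n = sum(len(s) for s in sets)
    labels = np.full(n, -1, dtype=np.int64)
    for ci, idx in enumerate(sets):
        labels[idx] = ci
    return labels


def split_by_class(patches: Sequence[Patch]) -> tuple[np.ndarray, np.ndarray]:
    """Return (benign_values, malignant_values) as flattened (n, m*m) arrays."""
    ben, mal = [], []
    for p in patches:
        if p.label == "benign":
            ben.append(p.values.ravel())
        elif p.label == "malignant":
            mal.append(p.values.ravel())
        else:
            raise ValidationError(
                f"patch from image {p.image_id!r} has no class label; "
                "reference learning requires labeled patches"
            )
    m = patches[0].side if patches else 0
    to_arr = lambda rows: (
        np.array(rows, dtype=np.float64) if rows else np.empty((0, m * m))
    )
    return to_arr(ben), to_arr(mal)


def init_references(
    patches: Sequence[Patch], k: int, r: int, seed: int
) -> LocalReferenceSet:
    """Seeded random initialization: sample k benign and r malignant patches
    without replacement and copy them as the initial references."""
    ben, mal = split_by_class(patches)
    if k < 1 or r < 1:
        raise ValidationError(f"k and r must be >= 1, got k={k}, r={r}")
    if len(ben) < k:
        raise ValidationError(
            f"k={k} benign references requested but only {len(ben)} benign patches"
        )
    if len(mal) < r:
        raise ValidationError(
            f"r={r} malignant references requested but only {len(mal)} malignant patches"
        )
    m = patches[0].side
    # independent per-class streams: each class's initialization depends
    # only on its own patch pool (exact class decoupling)
    bsel = np.random.default_rng(seed).choice(len(ben), size=k, replace=False)
    msel = np.random.default_rng(seed).choice(len(mal), size=r, replace=False)
    return LocalReferenceSet(
        benign=ben[bsel].reshape(k, m, m).copy(),
        malignant=mal[msel].reshape(r, m, m).copy(),
        meta={"seed": seed},
    )


def _nearest(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of nearest centroid per row; argmin ties go to the lowest index."""
    d = cdist(values, centroids.reshape(centroids.shape[0], -1), metric="sqeuclidean")
    return np.argmin(d, axis=1)


def assign_patches(
    patches: Sequence[Patch], refs: LocalReferenceSet
) -> ClusterAssignment:
    """Assign every patch to the nearest same-class reference (squared
    Euclidean distance on flattened intensities)."""
    ben, mal = split_by_class(patches)
    side = patches[0].side if patches else refs.m
    if side != refs.m:
        raise ValidationError(
            f"patch side {side} does not match reference side {refs.m}"
        )
    blab = _nearest(ben, refs.benign) if len(ben) else np.empty(0, dtype=np.int64)
    mlab = _nearest(mal, refs.malignant) if len(mal) else np.empty(0, dtype=np.int64)
    return ClusterAssignment(
        benign_sets=[np.flatnonzero(blab == i) for i in range(refs.k)],
        malignant_sets=[np.flatnonzero(mlab == i) for i in range(refs.r)],
    )


def _update_class(
    values: np.ndarray, sets: list[np.ndarray], centroids: np.ndarray
) -> np.ndarray:
    """Mean update with farthest-point repair for emptied clusters."""
    m = centroids.shape[1]
    new = centroids.reshape(centroids.shape[0], -1).copy()
    empty = []
    for i, idx in enumerate(sets):
        if len(idx):
            new[i] = values[idx].mean(axis=0)
        else:
            empty.append(i)
    for i in empty:
        # farthest in-class patch from its nearest current reference
        d = cdist(values, new, metric="sqeuclidean").min(axis=1)
        new[i] = values[int(np.argmax(d))]
    return new.reshape(centroids.shape)


def update_references(
    patches: Sequence[Patch],
    assignment: ClusterAssignment,
    refs: LocalReferenceSet,
) -> LocalReferenceSet:
    """Centroid update: each reference becomes the elementwise mean of its
    assigned patches; emptied references are re-seeded by the repair rule."""
    ben, mal = split_by_class(patches)
    return LocalReferenceSet(
        benign=_update_class(ben, assignment.benign_sets, refs.benign),
        malignant=_update_class(mal, assignment.malignant_sets, refs.malignant),
        meta=dict(refs.meta),
    )


def objective_value(
    patches: Sequence[Patch],
    refs: LocalReferenceSet,
    assignment: ClusterAssignment,
) -> float:
    """Class-guided distance objective: the sum over both classes of squared
    distances from each patch to its assigned same-class reference.  The
    class indicators remove every cross-class term, so only within-class
    distances contribute."""
    ben, mal = split_by_class(patches)
    total = 0.0
    for values, sets, cents in (
        (ben, assignment.benign_sets, refs.benign),
        (mal, assignment.malignant_sets, refs.malignant),
    ):
        flat = cents.reshape(cents.shape[0], -1)
        for i, idx in enumerate(sets):
            if len(idx):
                diff = values[idx] - flat[i]
                total += float(np.sum(diff * diff))
    return total


def learn_local_references(
    patches: Sequence[Patch],
    k: int,
    r: int,
    seed: int = 0,
    max_iter: int = 300,
) -> LocalReferenceSet:
    """Full reference learning: seeded init, then alternate assignment and
    centroid update until the assignment stabilizes (or ``max_iter``).

    The returned set's ``meta`` records ``seed``, ``iterations``,
    ``final_objective`` and the per-iteration ``objective_trace`` (the
    objective after each centroid update, a non-increasing sequence).
    """
    refs = init_references(patches, k=k, r=r, seed=seed)
    prev_labels: Optional[tuple[np.ndarray, np.ndarray]] = None
    trace: list[float] = []
    iterations = 0
    assignment = assign_patches(patches, refs)
    for iterations in range(1, max_iter + 1):
        refs = update_references(patches, assignment, refs)
        new_assignment = assign_patches(patches, refs)
        trace.append(objective_value(patches, refs, new_assignment))
        new_labels = new_assignment.labels()
        if prev_labels is not None and all(
            np.array_equal(a, b) for a, b in zip(prev_labels, new_labels)
        ):
            assignment = new_assignment
            break
        prev_labels = new_labels
        assignment = new_assignment
    refs.meta.update(
        {
            "seed": seed,
            "iterations": iterations,
            "final_objective": trace[-1] if trace else 0.0,
            "objective_trace": trace,
        }
    )
    return refs
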