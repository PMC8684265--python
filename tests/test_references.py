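"""Class-guided reference learning: assignment, updates, objective, Lloyd
properties, and equivalence with an exhaustive-partition oracle."""

import itertools

import numpy as np
import pytest

from lrscnet import (
    ValidationError,
    assign_patches,
    init_references,
    learn_local_references,
    objective_value,
    update_references,
)
from lrscnet.references import LocalReferenceSet

from conftest import pixel_patch, random_patches


def brute_force_min_objective(values: np.ndarray, k: int) -> float:
    """Global minimum of the within-class k-means objective by exhaustive
    enumeration of all assignments of n points to k clusters."""
    n = len(values)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        total = 0.0
        for c in range(k):
            members = values[[i for i in range(n) if assign[i] == c]]
            if len(members):
                mu = members.mean(axis=0)
                total += float(((members - mu) ** 2).sum())
        best = min(best, total)
    return best


class TestInit:
    def test_single_patch_becomes_reference(self):
        patches = [pixel_patch(0.3, "benign"), pixel_patch(0.7, "malignant")]
        refs = init_references(patches, k=1, r=1, seed=0)
        assert refs.benign[0, 0, 0] == 0.3
        assert refs.malignant[0, 0, 0] == 0.7

    def test_same_seed_same_init(self):
        rng = np.random.default_rng(0)
        patches = random_patches(rng, 6, side=4) + random_patches(rng, 6, side=4, label="malignant")
        a = init_references(patches, k=3, r=2, seed=42)
        b = init_references(patches, k=3, r=2, seed=42)
        assert np.array_equal(a.benign, b.benign) and np.array_equal(a.malignant, b.malignant)

    def test_too_few_patches_rejected_with_counts(self):
        patches = [pixel_patch(0.1, "benign"), pixel_patch(0.2, "benign"),
                   pixel_patch(0.9, "malignant")]
        with pytest.raises(ValidationError, match="k=3.*2 benign"):
            init_references(patches, k=3, r=1, seed=0)


class TestAssignUpdateObjective:
    def _refs(self, ben_vals, mal_vals):
        return LocalReferenceSet(
            benign=np.array(ben_vals).reshape(-1, 1, 1),
            malignant=np.array(mal_vals).reshape(-1, 1, 1),
        )

    def test_nearest_reference_assignment(self):
        patches = [pixel_patch(0.0, "benign"), pixel_patch(1.0, "benign"),
                   pixel_patch(0.5, "malignant")]
        refs = self._refs([0.1, 0.9], [0.5])
        a = assign_patches(patches, refs)
        # indices are within-class: the malignant patch is index 0 of the
        # malignant subset
        assert a.benign_sets[0].tolist() == [0]
        assert a.benign_sets[1].tolist() == [1]
        assert a.malignant_sets[0].tolist() == [0]

    def test_equidistant_tie_breaks_to_lowest_index(self):
        patches = [pixel_patch(0.5, "benign"), pixel_patch(0.2, "malignant")]
        refs = self._refs([0.4, 0.6], [0.2])
        a = assign_patches(patches, refs)
        assert a.benign_sets[0].tolist() == [0]
        assert a.benign_sets[1].tolist() == []

    def test_mean_update(self):
        patches = [pixel_patch(0.2, "benign"), pixel_patch(0.4, "benign"),
                   pixel_patch(0.8, "malignant")]
        refs = self._refs([0.0], [0.9])
        a = assign_patches(patches, refs)
        new = update_references(patches, a, refs)
        assert new.benign[0, 0, 0] == pytest.approx(0.3)
        assert new.malignant[0, 0, 0] == pytest.approx(0.8)

    def test_empty_cluster_repaired_never_nan(self):
        # both benign patches nearest ref 0 -> ref 1 empties and is re-seeded
        patches = [pixel_patch(0.0, "benign"), pixel_patch(0.1, "benign"),
                   pixel_patch(0.5, "malignant")]
        refs = self._refs([0.05, 0.9], [0.5])
        a = assign_patches(patches, refs)
        assert a.benign_sets[1].tolist() == []
        new = update_references(patches, a, refs)
        assert np.isfinite(new.benign).all()
        # repair picks the in-class patch farthest from its nearest reference
        assert new.benign[1, 0, 0] in (0.0, 0.1)

    def test_objective_zero_when_patches_equal_references(self):
        patches = [pixel_patch(0.2, "benign"), pixel_patch(0.7, "malignant")]
        refs = self._refs([0.2], [0.7])
        a = assign_patches(patches, refs)
        assert objective_value(patches, refs, a) == 0.0

    def test_objective_single_benign_distance(self):
        patches = [pixel_patch(0.0, "benign"), pixel_patch(0.7, "malignant")]
        refs = self._refs([0.5], [0.7])
        a = assign_patches(patches, refs)
        assert objective_value(patches, refs, a) == pytest.approx(0.25)

    def test_objective_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        patches = random_patches(rng, 5, side=3) + random_patches(rng, 5, side=3, label="malignant")
        refs = init_references(patches, k=2, r=2, seed=1)
        a = assign_patches(patches, refs)
        # independent double-loop summation
        expected = 0.0
        pools = {"benign": [p for p in patches if p.label == "benign"],
                 "malignant": [p for p in patches if p.label == "malignant"]}
        for cls, sets, cents in (
            ("benign", a.benign_sets, refs.benign),
            ("malignant", a.malignant_sets, refs.malignant),
        ):
            for i, idx in enumerate(sets):
                for j in idx:
                    expected += float(((pools[cls][j].values - cents[i]) ** 2).sum())
        assert objective_value(patches, refs, a) == pytest.approx(expected)


class TestLearn:
    def test_two_cluster_split_of_four_points(self):
        patches = [pixel_patch(v, "benign") for v in (0.0, 0.1, 0.9, 1.0)]
        patches += [pixel_patch(0.5, "malignant")]
        # try seeds until init picks one low and one high patch; the converged
        # centroids must be the two pair means
        for seed in range(20):
            refs = learn_local_references(patches, k=2, r=1, seed=seed, max_iter=50)
            cents = sorted(refs.benign.ravel().tolist())
            if cents == pytest.approx([0.05, 0.95]):
                break
        assert cents == pytest.approx([0.05, 0.95])

    def test_k_equals_n_reaches_zero_objective(self):
        patches = [pixel_patch(v, "benign") for v in (0.1, 0.4, 0.8)]
        patches += [pixel_patch(0.5, "malignant")]
        refs = learn_local_references(patches, k=3, r=1, seed=0, max_iter=50)
        assert refs.meta["final_objective"] == pytest.approx(0.0)
        assert sorted(refs.benign.ravel().tolist()) == pytest.approx([0.1, 0.4, 0.8])

    def test_class_pools_swap_swaps_reference_sets(self):
        rng = np.random.default_rng(5)
        ben = random_patches(rng, 6, side=2, label="benign")
        mal = random_patches(rng, 6, side=2, label="malignant")
        fwd = learn_local_references(ben + mal, k=2, r=2, seed=3, max_iter=50)
        # relabel: benign pool becomes malignant and vice versa
        ben_as_mal = [type(p)(values=p.values, origin=p.origin, image_id=p.image_id,
                              label="malignant") for p in ben]
        mal_as_ben = [type(p)(values=p.values, origin=p.origin, image_id=p.image_id,
                              label="benign") for p in mal]
        rev = learn_local_references(mal_as_ben + ben_as_mal, k=2, r=2, seed=3, max_iter=50)
        assert np.allclose(np.sort(fwd.benign.ravel()), np.sort(rev.malignant.ravel()))
        assert np.allclose(np.sort(fwd.malignant.ravel()), np.sort(rev.benign.ravel()))

    def test_benign_refs_depend_only_on_benign_patches(self):
        rng = np.random.default_rng(6)
        ben = random_patches(rng, 8, side=2, label="benign")
        mal1 = random_patches(rng, 8, side=2, label="malignant")
        mal2 = random_patches(rng, 8, side=2, label="malignant")
        a = learn_local_references(ben + mal1, k=2, r=2, seed=9, max_iter=50)
        b = learn_local_references(ben + mal2, k=2, r=2, seed=9, max_iter=50)
        assert np.allclose(a.benign, b.benign)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            patches = (
                [pixel_patch(v, "benign") for v in rng.random(8)]
                + [pixel_patch(v, "malignant") for v in rng.random(8)]
            )
            refs = learn_local_references(patches, k=3, r=2, seed=trial, max_iter=100)
            trace = refs.meta["objective_trace"]
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_references_stay_in_class_convex_hull(self):
        rng = np.random.default_rng(8)
        patches = random_patches(rng, 10, side=3) + random_patches(
            rng, 10, side=3, label="malignant"
        )
        refs = learn_local_references(patches, k=3, r=3, seed=0, max_iter=100)
        ben_vals = np.stack([p.values for p in patches if p.label == "benign"])
        assert refs.benign.min() >= ben_vals.min() - 1e-12
        assert refs.benign.max() <= ben_vals.max() + 1e-12

    def test_never_beats_exhaustive_optimum_small_instances(self):
        rng = np.random.default_rng(9)
        hits = 0
        trials = 15
        for t in range(trials):
            vals = rng.random(7)
            patches = [pixel_patch(v, "benign") for v in vals[:4]]
            patches += [pixel_patch(v, "malignant") for v in vals[4:]]
            refs = learn_local_references(patches, k=2, r=2, seed=t, max_iter=100)
            opt = brute_force_min_objective(vals[:4].reshape(-1, 1), 2)
            opt += brute_force_min_objective(vals[4:].reshape(-1, 1), 2)
            got = refs.meta["final_objective"]
            assert got >= opt - 1e-10
            hits += got <= opt + 1e-10
        assert hits >= 1  # random restarts find the optimum at least sometimes

    def test_roundtrip_serialization(self, tmp_path, tiny_refs):
        tiny_refs.save(tmp_path)
        loaded = LocalReferenceSet.load(tmp_path)
        assert np.array_equal(loaded.benign, tiny_refs.benign)
        assert loaded.meta["k"] == tiny_refs.k
        assert loaded.meta["iterations"] == tiny_refs.meta["iterations"]
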