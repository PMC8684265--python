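"""Contracts of the similarity encoder: tied features, |a-b| combination,
softmax similarity, pair construction, and the training loop."""

import numpy as np
import pytest

from lrscnet import (
    TrainConfig,
    ValidationError,
    cnn_features,
    combine_features,
    load_encoder,
    local_similarity_feature,
    make_pairs,
    save_encoder,
    similarity,
    train_encoder,
)
from lrscnet import encoder as enc
from lrscnet.patches import Patch

from conftest import random_patches


@pytest.fixture(scope="module")
def params():
    rng = np.random.default_rng(0)
    return enc.init_backbone(rng), enc.init_head(rng)


def _zero_head(widths=(64, 64)):
    head = enc.init_head(np.random.default_rng(0), widths)
    head.params = {k: np.zeros_like(v) for k, v in head.params.items()}
    return head


class TestFeatures:
    def test_feature_length_is_32_for_any_side(self, params):
        bb, _ = params
        rng = np.random.default_rng(1)
        for side in (8, 16, 24, 33):
            assert cnn_features(rng.random((side, side)), bb).shape == (32,)

    def test_input_below_minimum_side_rejected(self, params):
        bb, _ = params
        with pytest.raises(ValidationError, match=">= 8"):
            cnn_features(np.zeros((7, 7)), bb)

    def test_tied_parameters_one_function(self, params):
        # "both pipelines" are literally the same function: identical
        # features for the same input, however it is passed
        bb, _ = params
        x = np.random.default_rng(2).random((16, 16))
        patch = Patch(values=x, origin=(0, 0), image_id="a")
        assert np.allclose(cnn_features(patch, bb), cnn_features(x, bb))

    def test_eval_mode_deterministic(self, params):
        bb, _ = params
        x = np.random.default_rng(3).random((16, 16))
        assert np.array_equal(cnn_features(x, bb), cnn_features(x, bb))


class TestCombine:
    def test_identity_gives_zero(self):
        a = np.random.default_rng(0).random(32)
        assert np.all(combine_features(a, a) == 0)

    def test_absolute_difference(self):
        assert combine_features(np.array([0.2, 0.5]), np.array([0.7, 0.1])) == pytest.approx(
            [0.5, 0.4]
        )

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(32), rng.random(32)
        assert np.array_equal(combine_features(a, b), combine_features(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            combine_features(np.zeros(3), np.zeros(4))


class TestSimilarity:
    def test_zero_head_gives_half(self, params):
        bb, _ = params
        rng = np.random.default_rng(5)
        s = similarity(rng.random((16, 16)), rng.random((16, 16)), bb, _zero_head())
        assert s == pytest.approx(0.5)

    def test_symmetric_in_arguments(self, params):
        bb, head = params
        rng = np.random.default_rng(6)
        x, l = rng.random((16, 16)), rng.random((16, 16))
        assert similarity(x, l, bb, head) == pytest.approx(similarity(l, x, bb, head), abs=1e-6)

    def test_range_over_random_draws(self, params):
        bb, head = params
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = similarity(rng.random((8, 8)), rng.random((8, 8)), bb, head)
            assert 0.0 <= s <= 1.0

    def test_f_ls_length_and_elementwise_definition(self, params, tiny_refs):
        bb, head = params
        rng = np.random.default_rng(8)
        patch = rng.random((16, 16))
        f_ls = local_similarity_feature(patch, tiny_refs, bb, head)
        assert f_ls.shape == (tiny_refs.k + tiny_refs.r,)
        allr = tiny_refs.all_references()
        for i in (0, tiny_refs.k, tiny_refs.k + tiny_refs.r - 1):
            assert f_ls[i] == pytest.approx(similarity(patch, allr[i], bb, head), abs=1e-6)


class TestPairs:
    def test_labels_follow_class_agreement(self, tiny_patch_pool, tiny_refs):
        pairs = make_pairs(tiny_patch_pool, tiny_refs, n_pairs=64, seed=0)
        for pe in pairs:
            assert pe.relation_label == int(pe.patch.label == pe.reference_label)

    def test_balance_and_determinism(self, tiny_patch_pool, tiny_refs):
        a = make_pairs(tiny_patch_pool, tiny_refs, n_pairs=100, seed=3)
        b = make_pairs(tiny_patch_pool, tiny_refs, n_pairs=100, seed=3)
        assert sum(p.relation_label for p in a) == 50
        assert all(
            np.array_equal(x.patch.values, y.patch.values)
            and np.array_equal(x.reference, y.reference)
            and x.relation_label == y.relation_label
            for x, y in zip(a, b)
        )

    def test_single_class_pool_rejected(self, tiny_refs):
        rng = np.random.default_rng(9)
        with pytest.raises(ValidationError):
            make_pairs(random_patches(rng, 5), tiny_refs, n_pairs=10, seed=0)


class TestTraining:
    def test_zero_epochs_returns_init_unchanged(self, tiny_patch_pool, tiny_refs):
        cfg = TrainConfig(epochs=0, seed=11)
        bb, head, history = train_encoder(tiny_patch_pool, tiny_refs, cfg)
        rng = np.random.default_rng(11)
        bb0 = enc.init_backbone(rng)
        head0 = enc.init_head(rng, cfg.hidden_widths)
        assert history == []
        assert all(np.array_equal(bb.params[k], bb0.params[k]) for k in bb.params)
        assert all(np.array_equal(head.params[k], head0.params[k]) for k in head.params)

    def test_loss_history_finite_with_epoch_length(self, tiny_encoder):
        *_, history = tiny_encoder
        assert len(history) == 2
        assert all(np.isfinite(h) for h in history)

    def test_separable_classes_reach_high_pair_accuracy(self):
        # two constant-intensity classes far apart: the relation task is
        # near-trivial, so training must fit it
        rng = np.random.default_rng(12)
        patches = [
            Patch(values=np.full((16, 16), 0.1) + 0.01 * rng.random((16, 16)),
                  origin=(0, 0), image_id=f"b{i}", label="benign")
            for i in range(20)
        ] + [
            Patch(values=np.full((16, 16), 0.9) - 0.01 * rng.random((16, 16)),
                  origin=(0, 0), image_id=f"m{i}", label="malignant")
            for i in range(20)
        ]
        from lrscnet import learn_local_references

        refs = learn_local_references(patches, k=2, r=2, seed=0, max_iter=50)
        cfg = TrainConfig(epochs=10, pairs_per_epoch=512, seed=0)
        bb, head, _ = train_encoder(patches, refs, cfg)
        pairs = make_pairs(patches, refs, n_pairs=200, seed=99)
        correct = sum(
            (similarity(pe.patch, pe.reference, bb, head) >= 0.5) == bool(pe.relation_label)
            for pe in pairs
        )
        assert correct / len(pairs) >= 0.95

    def test_training_fully_seeded(self, tiny_patch_pool, tiny_refs):
        cfg = TrainConfig(epochs=1, pairs_per_epoch=128, seed=5)
        bb1, head1, h1 = train_encoder(tiny_patch_pool, tiny_refs, cfg)
        bb2, head2, h2 = train_encoder(tiny_patch_pool, tiny_refs, cfg)
        assert h1 == h2
        assert all(np.array_equal(bb1.params[k], bb2.params[k]) for k in bb1.params)

    def test_label_shuffled_pairs_learn_nothing(self, tiny_patch_pool, tiny_refs):
        # destroy the class signal by shuffling patch labels; held-out pair
        # accuracy should hover near chance (no leakage path)
        rng = np.random.default_rng(13)
        labels = [p.label for p in tiny_patch_pool]
        accs = []
        for seed in range(3):
            perm = rng.permutation(len(labels))
            shuffled = [
                Patch(values=p.values, origin=p.origin, image_id=p.image_id,
                      label=labels[perm[i]])
                for i, p in enumerate(tiny_patch_pool)
            ]
            cfg = TrainConfig(epochs=3, pairs_per_epoch=256, seed=seed)
            bb, head, _ = train_encoder(shuffled, tiny_refs, cfg)
            pairs = make_pairs(shuffled, tiny_refs, n_pairs=200, seed=1000 + seed)
            acc = np.mean([
                (similarity(pe.patch, pe.reference, bb, head) >= 0.5) == bool(pe.relation_label)
                for pe in pairs
            ])
            accs.append(acc)
        assert 0.35 <= np.mean(accs) <= 0.65


def test_encoder_roundtrip_serialization(tmp_path, tiny_encoder):
    bb, head, history = tiny_encoder
    save_encoder(tmp_path, bb, head, meta={"epoch_losses": history})
    bb2, head2, meta = load_encoder(tmp_path)
    assert all(np.array_equal(bb.params[k], bb2.params[k]) for k in bb.params)
    assert all(np.array_equal(bb.running[k], bb2.running[k]) for k in bb.running)
    assert all(np.array_equal(head.params[k], head2.params[k]) for k in head.params)
    assert meta["epoch_losses"] == history
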