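"""Shared fixtures: tiny labeled patch pools and a small trained encoder."""

import numpy as np
import pytest

from lrscnet import (
    PatchConfig,
    SynthSpec,
    TrainConfig,
    generate_images,
    learn_local_references,
    train_encoder,
)
from lrscnet.patches import Patch, extract_patches_cfg


def pixel_patch(value: float, label=None, image_id="img") -> Patch:
    """A 1x1 patch — the smallest unit for clustering arithmetic."""
    return Patch(values=np.array([[value]]), origin=(0, 0), image_id=image_id, label=label)


def random_patches(rng, n, side=16, label="benign"):
    return [
        Patch(values=rng.random((side, side)), origin=(0, 0), image_id=f"p{i}", label=label)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def tiny_spec():
    """A small, fast synthetic study: 6 images/class at 64 px."""
    return SynthSpec(image_side=64, n_per_class=6, seed=7)


@pytest.fixture(scope="session")
def tiny_images(tiny_spec):
    return generate_images(tiny_spec)


@pytest.fixture(scope="session")
def tiny_patch_pool(tiny_images):
    cfg = PatchConfig(m=16, stride=8)
    patches = []
    for img in tiny_images:
        patches.extend(extract_patches_cfg(img, cfg))
    return patches


@pytest.fixture(scope="session")
def tiny_refs(tiny_patch_pool):
    return learn_local_references(tiny_patch_pool, k=3, r=3, seed=0, max_iter=50)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_patch_pool, tiny_refs):
    """A briefly trained encoder — enough for contract tests, not accuracy."""
    cfg = TrainConfig(epochs=2, pairs_per_epoch=256, seed=0)
    bb, head, history = train_encoder(tiny_patch_pool, tiny_refs, cfg)
    return bb, head, history
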