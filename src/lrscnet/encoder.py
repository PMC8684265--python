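"""The similarity encoder: tied-parameter CNN backbone + relation head.

Two identical pipelines — one fed a local patch, one fed a local
reference — share a single parameter set (they are literally one
function), so "both pipelines" below always means one
:class:`BackboneParams`.  The backbone is three blocks of
[3x3 conv (32 filters, same padding) -> batch norm -> ReLU -> 2x2 max
pool] followed by global average pooling, giving a 32-long feature for
any input side >= 8.

The similarity head consumes the elementwise absolute difference of the
two features, applies two ReLU fully connected layers, and ends in a
2-unit softmax; the probability of the "related" unit is the similarity
s in [0, 1].  Because |a - b| is symmetric and every later layer is
shared, s(x, l) = s(l, x) exactly.

Training is supervised relation learning: a pair (patch, reference) is
labeled 1 when their classes agree and 0 otherwise, and the 2-way
cross-entropy is minimized by SGD with momentum and L2 weight decay
(defaults 0.001 / 0.9 / 1e-6).  References are frozen during training —
clustering precedes encoder training in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import nn
from .exceptions import ValidationError
from .patches import Patch
from .references import LocalReferenceSet

__all__ = [
    "BackboneParams",
    "SimilarityHeadParams",
    "TrainConfig",
    "PairExample",
    "init_backbone",
    "init_head",
    "cnn_features",
    "combine_features",
    "similarity",
    "local_similarity_feature",
    "local_similarity_matrix",
    "make_pairs",
    "train_encoder",
    "save_encoder",
    "load_encoder",
]

N_FILTERS = 32
MIN_SIDE = 8  # three 2x2 poolings need at least 8 pixels per side
RELATED_UNIT = 1  # softmax unit whose probability is the similarity s


@dataclass
class BackboneParams:
    """Parameters of the (single, tied) convolutional feature extractor.

    ``params`` maps names to arrays: convW{1..3}/convb{1..3} plus batch
    norm gamma/beta; ``running`` holds the batch-norm running mean/var
    used in eval mode.
    """

    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]

    def copy(self) -> "BackboneParams":
        return BackboneParams(
            params={k: v.copy() for k, v in self.params.items()},
            running={k: v.copy() for k, v in self.running.items()},
        )


@dataclass
class SimilarityHeadParams:
    """Two ReLU hidden layers plus the final 2-unit (softmax) layer."""

    params: dict[str, np.ndarray]

    @property
    def hidden_widths(self) -> tuple[int, int]:
        return (self.params["W1"].shape[1], self.params["W2"].shape[1])

    def copy(self) -> "SimilarityHeadParams":
        return SimilarityHeadParams({k: v.copy() for k, v in self.params.items()})


@dataclass
class TrainConfig:
    """Hyperparameters of the relation-learning loop.

    learning_rate / momentum / weight_decay default to 0.001 / 0.9 /
    1e-6.  ``pairs_per_epoch`` pairs are resampled each epoch with a
    50/50 relation-label balance; ``seed`` drives every stochastic
    choice (initialization, pair sampling, shuffling).
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    pairs_per_epoch: int = 2048
    hidden_widths: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.pairs_per_epoch < 1:
            raise ValidationError("learning_rate, batch_size and pairs_per_epoch must be positive")


@dataclass
class PairExample:
    """A (patch, reference) training pair with its relation label:
    1 if the patch's class equals the reference's class, else 0."""

    patch: Patch
    reference: np.ndarray
    reference_label: str
    relation_label: int


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_backbone(rng: np.random.Generator) -> BackboneParams:
    params: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    c_in = 1
    for i in (1, 2, 3):
        params[f"convW{i}"] = nn.he_init(rng, c_in * 9, (c_in * 9, N_FILTERS))
        params[f"convb{i}"] = np.zeros(N_FILTERS, dtype=nn.DTYPE)
        params[f"bn_gamma{i}"] = np.ones(N_FILTERS, dtype=nn.DTYPE)
        params[f"bn_beta{i}"] = np.zeros(N_FILTERS, dtype=nn.DTYPE)
        running[f"bn_rm{i}"] = np.zeros(N_FILTERS, dtype=nn.DTYPE)
        running[f"bn_rv{i}"] = np.ones(N_FILTERS, dtype=nn.DTYPE)
        c_in = N_FILTERS
    return BackboneParams(params=params, running=running)


def init_head(rng: np.random.Generator, hidden_widths: tuple[int, int] = (64, 64)) -> SimilarityHeadParams:
    h1, h2 = hidden_widths
    return SimilarityHeadParams(
        params={
            "W1": nn.he_init(rng, N_FILTERS, (N_FILTERS, h1)),
            "b1": np.zeros(h1, dtype=nn.DTYPE),
            "W2": nn.he_init(rng, h1, (h1, h2)),
            "b2": np.zeros(h2, dtype=nn.DTYPE),
            "W3": nn.he_init(rng, h2, (h2, 2)),
            "b3": np.zeros(2, dtype=nn.DTYPE),
        }
    )


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------

def _as_batch(x: Union[Patch, np.ndarray]) -> np.ndarray:
    values = np.asarray(x.values if isinstance(x, Patch) else x, dtype=nn.DTYPE)
    if values.ndim == 2:
        values = values[None]
    if values.ndim == 3:
        values = values[:, None]  # add channel axis
    return values


def backbone_forward(x: np.ndarray, bb: BackboneParams, train: bool):
    """(N, 1, H, W) -> ((N, 32) features, cache).  Train mode updates the
    batch-norm running statistics in place."""
    caches = []
    h = x
    p, run = bb.params, bb.running
    for i in (1, 2, 3):
        h, c_conv = nn.conv3x3_forward(h, p[f"convW{i}"], p[f"convb{i}"])
        h, c_bn, new_rm, new_rv = nn.bn_forward(
            h, p[f"bn_gamma{i}"], p[f"bn_beta{i}"], run[f"bn_rm{i}"], run[f"bn_rv{i}"], train
        )
        if train:
            run[f"bn_rm{i}"], run[f"bn_rv{i}"] = new_rm, new_rv
        h, c_relu = nn.relu_forward(h)
        h, c_pool = nn.maxpool2_forward(h)
        caches.append((c_conv, c_bn, c_relu, c_pool))
    feats, c_gap = nn.gap_forward(h)
    return feats, (caches, c_gap)


def backbone_backward(dfeats: np.ndarray, cache, bb: BackboneParams) -> dict[str, np.ndarray]:
    caches, c_gap = cache
    dh = nn.gap_backward(dfeats, c_gap)
    grads: dict[str, np.ndarray] = {}
    for i in (3, 2, 1):
        c_conv, c_bn, c_relu, c_pool = caches[i - 1]
        dh = nn.maxpool2_backward(dh, c_pool)
        dh = nn.relu_backward(dh, c_relu)
        dh, dgamma, dbeta = nn.bn_backward(dh, c_bn)
        grads[f"bn_gamma{i}"] = dgamma
        grads[f"bn_beta{i}"] = dbeta
        dh, dW, db = nn.conv3x3_backward(dh, c_conv)
        grads[f"convW{i}"] = dW
        grads[f"convb{i}"] = db
    return grads


def head_forward(v: np.ndarray, head: SimilarityHeadParams):
    """(N, 32) combined features -> ((N, 2) logits, cache)."""
    p = head.params
    h1, c1 = nn.linear_forward(v, p["W1"], p["b1"])
    a1, m1 = nn.relu_forward(h1)
    h2, c2 = nn.linear_forward(a1, p["W2"], p["b2"])
    a2, m2 = nn.relu_forward(h2)
    logits, c3 = nn.linear_forward(a2, p["W3"], p["b3"])
    return logits, (c1, m1, c2, m2, c3)


def head_backward(dlogits: np.ndarray, cache):
    c1, m1, c2, m2, c3 = cache
    grads: dict[str, np.ndarray] = {}
    da2, grads["W3"], grads["b3"] = nn.linear_backward(dlogits, c3)
    dh2 = nn.relu_backward(da2, m2)
    da1, grads["W2"], grads["b2"] = nn.linear_backward(dh2, c2)
    dh1 = nn.relu_backward(da1, m1)
    dv, grads["W1"], grads["b1"] = nn.linear_backward(dh1, c1)
    return dv, grads


# ---------------------------------------------------------------------------
# Public inference operations
# ---------------------------------------------------------------------------

def cnn_features(
    x: Union[Patch, np.ndarray], bb: BackboneParams, mode: str = "eval"
) -> np.ndarray:
    """Feature vector of length 32 for one patch/reference (or a stack).

    Eval mode (the default) uses batch-norm running statistics and is
    fully deterministic.  Raises on inputs smaller than 8x8.
    """
    batch = _as_batch(x)
    if batch.shape[-1] < MIN_SIDE or batch.shape[-2] < MIN_SIDE:
        raise ValidationError(
            f"backbone input side must be >= {MIN_SIDE}, got {batch.shape[-2:]}"
        )
    feats, _ = backbone_forward(batch, bb, train=(mode == "train"))
    single = isinstance(x, Patch) or np.asarray(
        x.values if isinstance(x, Patch) else x
    ).ndim == 2
    return feats[0] if single else feats


def combine_features(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference |a - b| (symmetric, nonnegative)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"feature shapes differ: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def similarity(
    patch: Union[Patch, np.ndarray],
    reference: np.ndarray,
    bb: BackboneParams,
    head: SimilarityHeadParams,
) -> float:
    """Learned similarity s in [0, 1] between a patch and a reference:
    probability of the 'related' softmax unit on |f(patch) - f(reference)|."""
    fa = cnn_features(patch, bb, mode="eval")
    fb = cnn_features(reference, bb, mode="eval")
    v = combine_features(fa, fb)[None]
    logits, _ = head_forward(v, head)
    return float(nn.softmax(logits)[0, RELATED_UNIT])


def local_similarity_matrix(
    patch_values: np.ndarray,
    refs: LocalReferenceSet,
    bb: BackboneParams,
    head: SimilarityHeadParams,
) -> np.ndarray:
    """Similarity of every patch to every reference.

    patch_values: (n, m, m).  Returns (n, k + r) with the k benign
    references in columns 0..k-1 followed by the r malignant ones —
    the F_ls ordering contract.
    """
    fp = cnn_features(patch_values, bb, mode="eval")  # (n, 32)
    fr = cnn_features(refs.all_references(), bb, mode="eval")  # (k+r, 32)
    v = np.abs(fp[:, None, :] - fr[None, :, :])  # (n, k+r, 32)
    n, kr, d = v.shape
    logits, _ = head_forward(v.reshape(n * kr, d), head)
    return nn.softmax(logits)[:, RELATED_UNIT].reshape(n, kr)


def local_similarity_feature(
    patch: Union[Patch, np.ndarray],
    refs: LocalReferenceSet,
    bb: BackboneParams,
    head: SimilarityHeadParams,
) -> np.ndarray:
    """F_ls for one patch: length k + r, benign block first, each in [0, 1]."""
    values = patch.values if isinstance(patch, Patch) else np.asarray(patch)
    return local_similarity_matrix(values[None], refs, bb, head)[0]


# ---------------------------------------------------------------------------
# Pair construction and training
# ---------------------------------------------------------------------------

def _class_indices(patches: Sequence[Patch]) -> dict[str, np.ndarray]:
    idx = {"benign": [], "malignant": []}
    for i, p in enumerate(patches):
        if p.label not in idx:
            raise ValidationError(
                f"patch from image {p.image_id!r} lacks a class label"
            )
        idx[p.label].append(i)
    return {c: np.array(v, dtype=np.int64) for c, v in idx.items()}


def _sample_pair_indices(
    rng: np.random.Generator,
    by_class: dict[str, np.ndarray],
    refs: LocalReferenceSet,
    n_pairs: int,
):
    """Balanced pair sampling.  Returns (patch_idx, ref_idx, labels) where
    ref_idx indexes refs.all_references().  Half the pairs are related
    (same class), half unrelated; patch class is drawn uniformly."""
    n_related = n_pairs // 2
    related = np.zeros(n_pairs, dtype=np.int64)
    related[:n_related] = 1
    rng.shuffle(related)
    patch_idx = np.empty(n_pairs, dtype=np.int64)
    ref_idx = np.empty(n_pairs, dtype=np.int64)
    ref_count = {"benign": refs.k, "malignant": refs.r}
    ref_offset = {"benign": 0, "malignant": refs.k}
    classes = np.array(["benign", "malignant"])
    patch_cls = classes[rng.integers(0, 2, size=n_pairs)]
    for t in range(n_pairs):
        pc = patch_cls[t]
        patch_idx[t] = by_class[pc][rng.integers(len(by_class[pc]))]
        rc = pc if related[t] else ("malignant" if pc == "benign" else "benign")
        ref_idx[t] = ref_offset[rc] + rng.integers(ref_count[rc])
    return patch_idx, ref_idx, related


def make_pairs(
    patches: Sequence[Patch],
    refs: LocalReferenceSet,
    n_pairs: int,
    seed: int,
) -> list[PairExample]:
    """Sample a balanced, seeded list of labeled (patch, reference) pairs."""
    by_class = _class_indices(patches)
    for cls, idx in by_class.items():
        if len(idx) == 0:
            raise ValidationError(f"no {cls} patches available for pair sampling")
    rng = np.random.default_rng(seed)
    pi, ri, rel = _sample_pair_indices(rng, by_class, refs, n_pairs)
    all_refs = refs.all_references()
    out = []
    for t in range(n_pairs):
        ref_label = "benign" if ri[t] < refs.k else "malignant"
        out.append(
            PairExample(
                patch=patches[pi[t]],
                reference=all_refs[ri[t]],
                reference_label=ref_label,
                relation_label=int(rel[t]),
            )
        )
    return out


def train_encoder(
    patches: Sequence[Patch],
    refs: LocalReferenceSet,
    config: TrainConfig,
) -> tuple[BackboneParams, SimilarityHeadParams, list[float]]:
    """Train backbone + head on the relation task by minibatch SGD.

    Each epoch draws ``config.pairs_per_epoch`` balanced pairs; each
    minibatch stacks patches and references through the shared backbone
    (train-mode batch norm), combines features by |a - b|, and descends
    the 2-way cross-entropy with momentum and weight decay.  Returns the
    trained parameters and the per-epoch mean loss history.  Fully
    deterministic given ``config.seed``.
    """
    by_class = _class_indices(patches)
    for cls, idx in by_class.items():
        if len(idx) < 2:
            raise ValidationError(
                f"training requires >= 2 patches per class, got {len(idx)} {cls}"
            )
    rng = np.random.default_rng(config.seed)
    bb = init_backbone(rng)
    head = init_head(rng, config.hidden_widths)
    decay = {f"convW{i}" for i in (1, 2, 3)} | {"W1", "W2", "W3"}
    opt_bb = nn.SGD(config.learning_rate, config.momentum, config.weight_decay,
                    {n for n in decay if n.startswith("conv")})
    opt_head = nn.SGD(config.learning_rate, config.momentum, config.weight_decay,
                      {"W1", "W2", "W3"})
    patch_stack = np.stack([p.values for p in patches])[:, None].astype(nn.DTYPE)
    ref_stack = refs.all_references()[:, None].astype(nn.DTYPE)

    history: list[float] = []
    for epoch in range(config.epochs):
        pi, ri, rel = _sample_pair_indices(rng, by_class, refs, config.pairs_per_epoch)
        losses = []
        for start in range(0, config.pairs_per_epoch, config.batch_size):
            sl = slice(start, min(start + config.batch_size, config.pairs_per_epoch))
            xb = patch_stack[pi[sl]]
            rb = ref_stack[ri[sl]]
            yb = rel[sl]
            B = xb.shape[0]
            stacked = np.concatenate([xb, rb], axis=0)
            feats, bb_cache = backbone_forward(stacked, bb, train=True)
            fa, fb = feats[:B], feats[B:]
            diff = fa - fb
            v = np.abs(diff)
            logits, h_cache = head_forward(v, head)
            loss, dlogits = nn.softmax_xent(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            losses.append(loss)
            dv, h_grads = head_backward(dlogits, h_cache)
            da = dv * np.sign(diff)
            dfeats = np.concatenate([da, -da], axis=0)
            bb_grads = backbone_backward(dfeats, bb_cache, bb)
            opt_bb.step(bb.params, bb_grads)
            opt_head.step(head.params, h_grads)
        history.append(float(np.mean(losses)))
    return bb, head, history


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_encoder(
    directory: Path | str,
    bb: BackboneParams,
    head: SimilarityHeadParams,
    meta: Optional[dict] = None,
    prefix: str = "encoder",
) -> Path:
    """Write all named parameter arrays (.npz) + JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"bb_{k}": v for k, v in bb.params.items()}
    arrays.update({f"run_{k}": v for k, v in bb.running.items()})
    arrays.update({f"head_{k}": v for k, v in head.params.items()})
    np.savez(directory / f"{prefix}.npz", **arrays)
    sidecar = directory / f"{prefix}.json"
    payload = {"hidden_widths": list(head.hidden_widths), "n_filters": N_FILTERS}
    if meta:
        payload.update(meta)
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def load_encoder(
    directory: Path | str, prefix: str = "encoder"
) -> tuple[BackboneParams, SimilarityHeadParams, dict]:
    directory = Path(directory)
    with np.load(directory / f"{prefix}.npz") as data:
        bb = BackboneParams(
            params={k[3:]: data[k].copy() for k in data.files if k.startswith("bb_")},
            running={k[4:]: data[k].copy() for k in data.files if k.startswith("run_")},
        )
        head = SimilarityHeadParams(
            params={k[5:]: data[k].copy() for k in data.files if k.startswith("head_")}
        )
    sidecar = directory / f"{prefix}.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return bb, head, meta
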