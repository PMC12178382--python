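"""Bag aggregation: average pooling and learnable attention (Hopfield) pooling.

Average pooling (AP) maps a bag to the elementwise mean of its patch
features — a fixed, nonparameterized set function. Hopfield pooling (HP) is
the parameterized alternative, realized here in its standard single-head
learnable-query attention form: with a query vector q, key projection K and
value projection V,

    alpha_i = softmax_i( beta * q . (K x_i) ),      y = sum_i alpha_i (V x_i)

so the slide vector y is an attention-weighted combination of projected
patch features, with beta an inverse temperature defaulting to 1/sqrt(k).
Both operators are permutation-invariant set functions and the attention
weights form a probability vector.

HP's parameters are trained by metric learning with the supervised
contrastive loss over L2-normalized slide outputs z = y/||y||:

    L = mean_i -(1/|P(i)|) sum_{p in P(i)} log[ exp(z_i.z_p/tau)
                                               / sum_{a != i} exp(z_i.z_a/tau) ]

where P(i) are the same-label slides in the batch. Gradients are
closed-form (hand-derived backpropagation through the attention softmax,
the projections and the normalization), verified against finite
differences, and optimized with plain SGD with momentum. Training is
deterministic under a fixed seed and keeps the lowest-loss checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence
import json

import numpy as np

from .features import PatchBag

__all__ = [
    "SlideVector",
    "PoolingModel",
    "TrainingConfig",
    "average_pool",
    "hopfield_pool",
    "init_pooling_model",
    "train_pooling",
    "contrastive_loss",
    "save_pooling_model",
    "load_pooling_model",
]


@dataclass
class SlideVector:
    """One aggregated representation per slide."""

    slide_id: str
    vector: np.ndarray
    pipeline_tag: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"slide vector for {self.slide_id} has NaN/Inf")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for contrastive HP training.

    tau is the contrastive temperature (0.1 default); epochs/lr/momentum
    drive plain SGD; batch_size slides are drawn per step. query_dim is k,
    output_dim is p (None keeps p = d so AP and HP stay comparable).
    """

    tau: float = 0.1
    epochs: int = 50
    lr: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 32
    query_dim: int = 64
    output_dim: int | None = None
    seed: int = 0


@dataclass
class PoolingModel:
    query: np.ndarray           # (k,)
    key_projection: np.ndarray  # (k, d)
    value_projection: np.ndarray  # (p, d)
    beta: float
    training_config: TrainingConfig | None = None
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.query = np.asarray(self.query, dtype=np.float64).ravel()
        self.key_projection = np.asarray(self.key_projection, dtype=np.float64)
        self.value_projection = np.asarray(self.value_projection, dtype=np.float64)
        k = self.query.shape[0]
        if self.key_projection.shape[0] != k:
            raise ValueError("key_projection rows must match query length")
        if self.key_projection.shape[1] != self.value_projection.shape[1]:
            raise ValueError("key and value projections must share input dim d")
        if not (self.beta > 0):
            raise ValueError("beta must be positive")
        for arr in (self.query, self.key_projection, self.value_projection):
            if not np.all(np.isfinite(arr)):
                raise ValueError("pooling parameters must be finite")

    @property
    def input_dim(self) -> int:
        return self.key_projection.shape[1]

    @property
    def output_dim(self) -> int:
        return self.value_projection.shape[0]

    def copy(self) -> "PoolingModel":
        return PoolingModel(
            query=self.query.copy(),
            key_projection=self.key_projection.copy(),
            value_projection=self.value_projection.copy(),
            beta=self.beta,
            training_config=self.training_config,
            loss_history=list(self.loss_history),
        )


def average_pool(bag: PatchBag, pipeline_tag: str = "") -> SlideVector:
    """Elementwise mean over the bag's rows (output length p = d)."""
    if bag.n_patches < 1:
        raise ValueError("cannot pool an empty bag")
    return SlideVector(
        slide_id=bag.slide_id,
        vector=bag.features.mean(axis=0, dtype=np.float64),
        pipeline_tag=pipeline_tag or f"{bag.extractor_name}+ap",
    )


def _attention(model: PoolingModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights alpha and scores s for a bag matrix X (n, d)."""
    scores = model.beta * (model.query @ (model.key_projection @ X.T))  # (n,)
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum(), scores


def hopfield_pool(
    model: PoolingModel, bag: PatchBag, pipeline_tag: str = ""
) -> SlideVector:
    """Attention-weighted pooling of projected patch features."""
    X = np.asarray(bag.features, dtype=np.float64)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"bag dimension {X.shape[1]} does not match model input "
            f"dimension {model.input_dim}"
        )
    alpha, _ = _attention(model, X)
    y = model.value_projection @ (X.T @ alpha)
    return SlideVector(
        slide_id=bag.slide_id,
        vector=y,
        pipeline_tag=pipeline_tag or f"{bag.extractor_name}+hp",
    )


def init_pooling_model(
    d: int, config: TrainingConfig | None = None
) -> PoolingModel:
    """Random Gaussian initialisation, scaled 1/sqrt(fan-in), seeded."""
    config = config or TrainingConfig()
    k = config.query_dim
    p = config.output_dim if config.output_dim is not None else d
    rng = np.random.default_rng(config.seed)
    return PoolingModel(
        query=rng.standard_normal(k) / np.sqrt(k),
        key_projection=rng.standard_normal((k, d)) / np.sqrt(d),
        value_projection=rng.standard_normal((p, d)) / np.sqrt(d),
        beta=1.0 / np.sqrt(k),
        training_config=config,
    )


def _normalize_rows(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Y, axis=1)
    norms = np.maximum(norms, 1e-12)
    return Y / norms[:, None], norms


def _supcon_loss_grad(
    Z: np.ndarray, labels: np.ndarray, tau: float
) -> tuple[float, np.ndarray]:
    """Supervised contrastive loss and its gradient w.r.t. the normalized
    embeddings Z (B, p). Anchors without a positive are skipped; the loss
    is averaged over the remaining anchors."""
    B = Z.shape[0]
    S = (Z @ Z.T) / tau
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    off = ~np.eye(B, dtype=bool)
    valid = same.any(axis=1)
    if not valid.any():
        return 0.0, np.zeros_like(Z)

    # log-softmax over j != i, row-wise
    S_off = np.where(off, S, -np.inf)
    m = S_off.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(S_off - m).sum(axis=1, keepdims=True))
    log_prob = S - lse  # only off-diagonal entries meaningful

    n_pos = same.sum(axis=1).astype(float)
    per_anchor = np.where(
        valid, -(np.where(same, log_prob, 0.0).sum(axis=1)) / np.maximum(n_pos, 1), 0.0
    )
    n_valid = int(valid.sum())
    loss = float(per_anchor.sum() / n_valid)

    softmax = np.where(off, np.exp(S - lse), 0.0)
    G = np.where(valid[:, None], softmax - same / np.maximum(n_pos, 1)[:, None], 0.0)
    G /= n_valid
    dZ = (G @ Z + G.T @ Z) / tau
    return loss, dZ


def contrastive_loss(
    model: PoolingModel,
    bags: Sequence[PatchBag],
    labels: Sequence[str],
    tau: float = 0.1,
) -> float:
    """Full-set supervised contrastive loss of the pooled, normalized outputs."""
    Y = np.stack([hopfield_pool(model, b).vector for b in bags])
    Z, _ = _normalize_rows(Y)
    loss, _ = _supcon_loss_grad(Z, np.asarray(labels, dtype=object), tau)
    return loss


def _batch_grads(
    model: PoolingModel,
    bags: Sequence[PatchBag],
    labels: np.ndarray,
    tau: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and parameter gradients for one batch of slides."""
    cache = []
    Y = np.empty((len(bags), model.output_dim))
    for b, bag in enumerate(bags):
        X = np.asarray(bag.features, dtype=np.float64)
        alpha, _ = _attention(model, X)
        h = X.T @ alpha  # (d,)
        Y[b] = model.value_projection @ h
        cache.append((X, alpha, h))
    Z, norms = _normalize_rows(Y)
    loss, dZ = _supcon_loss_grad(Z, labels, tau)

    gq = np.zeros_like(model.query)
    gK = np.zeros_like(model.key_projection)
    gV = np.zeros_like(model.value_projection)
    for b, (X, alpha, h) in enumerate(cache):
        g = dZ[b]
        dy = (g - (g @ Z[b]) * Z[b]) / norms[b]
        gV += np.outer(dy, h)
        dh = model.value_projection.T @ dy  # (d,)
        dalpha = X @ dh  # (n,)
        ds = alpha * (dalpha - alpha @ dalpha)  # softmax backward
        Xs = X.T @ ds  # (d,)
        gq += model.beta * (model.key_projection @ Xs)
        gK += model.beta * np.outer(model.query, Xs)
    return loss, gq, gK, gV


def train_pooling(
    bags: Sequence[PatchBag],
    labels: Sequence[str],
    config: TrainingConfig | None = None,
    model: PoolingModel | None = None,
) -> PoolingModel:
    """Train HP parameters with the supervised contrastive objective.

    Training bags only — never evaluation slides. Requires at least two
    classes. With ``epochs=0`` the initialized model is returned unchanged.
    Returns the checkpoint with the lowest epoch loss; ``loss_history``
    holds the mean batch loss per epoch.
    """
    config = config or TrainingConfig()
    labels = np.asarray(list(labels), dtype=object)
    if len(bags) != len(labels):
        raise ValueError("bags and labels must align")
    if len(set(labels.tolist())) < 2:
        raise ValueError("contrastive training needs at least two classes")
    d = bags[0].dim
    if model is None:
        model = init_pooling_model(d, config)
    else:
        model = model.copy()
    if config.epochs == 0:
        return model

    rng = np.random.default_rng(config.seed + 1)
    vel = {
        "q": np.zeros_like(model.query),
        "K": np.zeros_like(model.key_projection),
        "V": np.zeros_like(model.value_projection),
    }
    best = model.copy()
    best_loss = np.inf
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(bags))
        epoch_losses = []
        for start in range(0, len(bags), config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue
            batch_bags = [bags[i] for i in idx]
            batch_labels = labels[idx]
            loss, gq, gK, gV = _batch_grads(model, batch_bags, batch_labels, config.tau)
            epoch_losses.append(loss)
            vel["q"] = config.momentum * vel["q"] - config.lr * gq
            vel["K"] = config.momentum * vel["K"] - config.lr * gK
            vel["V"] = config.momentum * vel["V"] - config.lr * gV
            model.query = model.query + vel["q"]
            model.key_projection = model.key_projection + vel["K"]
            model.value_projection = model.value_projection + vel["V"]
        epoch_loss = float(np.mean(epoch_losses)) if epoch_losses else np.inf
        history.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best = model.copy()
    best.training_config = config
    best.loss_history = history
    return best


def save_pooling_model(model: PoolingModel, prefix: str | Path) -> tuple[Path, Path]:
    """Persist as JSON metadata + npz parameter blob."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    blob = prefix.with_suffix(".npz")
    meta = prefix.with_suffix(".json")
    np.savez(
        blob,
        query=model.query,
        key_projection=model.key_projection,
        value_projection=model.value_projection,
    )
    cfg = model.training_config
    meta.write_text(
        json.dumps(
            {
                "beta": model.beta,
                "loss_history": model.loss_history,
                "training_config": None if cfg is None else cfg.__dict__,
                "blob": blob.name,
            },
            indent=2,
        )
    )
    return meta, blob


def load_pooling_model(prefix: str | Path) -> PoolingModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as blob:
        params = {k: blob[k] for k in blob.files}
    cfg = meta["training_config"]
    return PoolingModel(
        query=params["query"],
        key_projection=params["key_projection"],
        value_projection=params["value_projection"],
        beta=meta["beta"],
        training_config=None if cfg is None else TrainingConfig(**cfg),
        loss_history=list(meta["loss_history"]),
    )
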