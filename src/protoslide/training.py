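"""Episodic (N-way K-shot) training of the embedding network.

Each episode samples ``Nc`` classes and, per class, ``Ns`` support and
``Nq`` query patches (disjoint, without replacement).  Supports are
embedded and clustered into ``k_ep`` prototypes per class; each query's
class logits are the negative minimum squared distances to the class
prototypes, and the loss is the mean categorical cross-entropy of their
softmax against the true class.  Gradients flow through both query and
support embeddings (prototypes are means of their assigned supports);
the k-means cluster assignments themselves are treated as constants
within an episode.

Training is fully seeded: episode sampling, augmentation, and weight
initialization use independent generator streams, so identical configs
reproduce identical loss trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, augment_batch
from .embedding import ReferenceBackbone, build_reference_backbone
from .nn import Adam
from .patches import PatchDataset
from .prototypes import kmeans_fit
from .synthetic import mix_seed

__all__ = [
    "TrainingSet",
    "EpisodeSpec",
    "Episode",
    "TrainingConfig",
    "TrainingResult",
    "TrainingDivergedError",
    "sample_episode",
    "episode_loss",
    "train",
    "select_best_checkpoint",
]


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite; carries epoch/episode diagnostics."""


class TrainingSet:
    """Labeled patch stack with per-class index lists."""

    def __init__(self, patches: np.ndarray, labels: Sequence[str]):
        patches = np.asarray(patches)
        if patches.ndim != 4 or patches.dtype != np.uint8:
            raise ValueError("patches must be a (N, H, W, 3) uint8 array")
        labels = np.asarray(labels, dtype=object)
        if len(labels) != patches.shape[0]:
            raise ValueError("label count does not match patch count")
        if patches.shape[0] == 0:
            raise ValueError("training set is empty")
        self.patches = patches
        self.labels = labels
        self.classes = sorted(set(map(str, labels)))
        self.class_indices = {
            c: np.flatnonzero(labels == c) for c in self.classes
        }
        if any(len(v) == 0 for v in self.class_indices.values()):
            raise ValueError("every class must be non-empty")

    @classmethod
    def from_dataset(cls, ds: PatchDataset) -> "TrainingSet":
        return cls(ds.pixel_stack(), ds.labels())

    @property
    def n(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]


@dataclass(frozen=True)
class EpisodeSpec:
    """Nc-way Ns-shot episode geometry with Nq queries and k_ep prototypes."""

    nc: int
    ns: int
    nq: int
    k_ep: int = 1

    def __post_init__(self) -> None:
        if self.nc < 1:
            raise ValueError("nc must be >= 1")
        if not self.ns >= self.k_ep >= 1:
            raise ValueError("need ns >= k_ep >= 1")
        if self.nq < 1:
            raise ValueError("nq must be >= 1")


@dataclass
class Episode:
    """One sampled task: support/query patches for a class subset.

    ``support_y``/``query_y`` hold within-episode class indices
    (0..Nc-1, positions in ``classes``); supports of episode-class ``i``
    occupy rows ``i * ns : (i + 1) * ns`` of ``support_x``.
    """

    classes: list[str]
    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    support_indices: np.ndarray
    query_indices: np.ndarray


def sample_episode(
    ts: TrainingSet, spec: EpisodeSpec, rng: np.random.Generator
) -> Episode:
    """Draw one episode without replacement; support and query sets disjoint."""
    eligible = [c for c in ts.classes if len(ts.class_indices[c]) >= spec.ns + spec.nq]
    if len(eligible) < spec.nc:
        raise ValueError(
            f"need {spec.nc} classes with >= {spec.ns + spec.nq} patches, "
            f"only {len(eligible)} eligible"
        )
    chosen = list(rng.choice(np.asarray(eligible, dtype=object), size=spec.nc, replace=False))
    support_idx, query_idx = [], []
    for c in chosen:
        take = rng.choice(ts.class_indices[c], size=spec.ns + spec.nq, replace=False)
        support_idx.append(take[: spec.ns])
        query_idx.append(take[spec.ns :])
    support_indices = np.concatenate(support_idx)
    query_indices = np.concatenate(query_idx)
    return Episode(
        classes=[str(c) for c in chosen],
        support_x=ts.patches[support_indices],
        support_y=np.repeat(np.arange(spec.nc), spec.ns),
        query_x=ts.patches[query_indices],
        query_y=np.repeat(np.arange(spec.nc), spec.nq),
        support_indices=support_indices,
        query_indices=query_indices,
    )


def _prototypical_loss_from_embeddings(
    s_emb: np.ndarray,
    q_emb: np.ndarray,
    spec: EpisodeSpec,
    kmeans_seed: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. support and query embeddings.

    Prototypes are k-means centers of each episode-class's supports
    (1 restart; assignments constant).  Returns
    ``(loss, d_loss/d_s_emb, d_loss/d_q_emb)``.
    """
    nc, ns = spec.nc, spec.ns
    s_emb = s_emb.astype(np.float64, copy=False)
    q_emb = q_emb.astype(np.float64, copy=False)
    n_q = q_emb.shape[0]

    centers_per_class: list[np.ndarray] = []
    assign_per_class: list[np.ndarray] = []
    counts_per_class: list[np.ndarray] = []
    for i in range(nc):
        x = s_emb[i * ns : (i + 1) * ns]
        centers, assign, _ = kmeans_fit(
            x, spec.k_ep, mix_seed(kmeans_seed, i), n_restarts=1
        )
        centers_per_class.append(centers)
        assign_per_class.append(assign)
        counts_per_class.append(np.bincount(assign, minlength=centers.shape[0]))

    # distances and nearest-prototype index per (query, class)
    dist = np.empty((n_q, nc))
    nearest = np.empty((n_q, nc), dtype=np.int64)
    for i in range(nc):
        c = centers_per_class[i]
        d2 = ((q_emb[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        nearest[:, i] = d2.argmin(axis=1)
        dist[:, i] = d2[np.arange(n_q), nearest[:, i]]

    logits = -dist
    logits -= logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    true = np.repeat(np.arange(nc), spec.nq)[:n_q]
    loss = float(-np.mean(np.log(probs[np.arange(n_q), true] + 1e-300)))

    one_hot = np.zeros_like(probs)
    one_hot[np.arange(n_q), true] = 1.0
    # dL/d dist = (one_hot - probs) / n_q  (logits are negative distances)
    ddist = (one_hot - probs) / n_q

    dq = np.zeros_like(q_emb)
    ds = np.zeros_like(s_emb)
    for i in range(nc):
        c = centers_per_class[i]
        diff = q_emb - c[nearest[:, i]]  # (n_q, d)
        w = ddist[:, i][:, None]
        dq += 2.0 * w * diff
        dcenters = np.zeros_like(c)
        np.add.at(dcenters, nearest[:, i], -2.0 * w * diff)
        # prototype j is the mean of its assigned supports
        counts = counts_per_class[i]
        per_support = dcenters[assign_per_class[i]] / counts[assign_per_class[i]][:, None]
        ds[i * ns : (i + 1) * ns] = per_support
    return loss, ds, dq


def episode_loss(
    episode: Episode,
    embedder: ReferenceBackbone,
    spec: EpisodeSpec,
    *,
    kmeans_seed: int = 0,
    augmentation: AugmentationPolicy | None = None,
    augment_rng: np.random.Generator | None = None,
    augment_targets: str = "both",
    want_grads: bool = False,
) -> float | tuple[float, list[np.ndarray]]:
    """Prototypical episode loss; with ``want_grads`` also d loss / d theta."""
    support_x, query_x = episode.support_x, episode.query_x
    if augmentation is not None:
        if augment_rng is None:
            raise ValueError("augmentation requires an rng")
        if augment_targets not in ("both", "supports", "queries"):
            raise ValueError("augment_targets must be both|supports|queries")
        if augment_targets in ("both", "supports"):
            support_x = augment_batch(support_x, augmentation, augment_rng)
        if augment_targets in ("both", "queries"):
            query_x = augment_batch(query_x, augmentation, augment_rng)

    n_s = support_x.shape[0]
    batch = np.concatenate([support_x, query_x], axis=0)
    emb = embedder.forward(batch, cache=want_grads)
    loss, ds, dq = _prototypical_loss_from_embeddings(
        emb[:n_s], emb[n_s:], spec, kmeans_seed
    )
    if not np.isfinite(loss):
        raise TrainingDivergedError(f"non-finite episode loss ({loss})")
    if not want_grads:
        return loss
    d_emb = np.concatenate([ds, dq], axis=0).astype(emb.dtype)
    grads = embedder.net.backward(d_emb)
    return loss, grads


@dataclass
class TrainingConfig:
    """Optimizer, schedule, augmentation, and seeding for a training run.

    ``learning_rate`` decays by the factor ``lr_decay`` after each epoch
    (exponential schedule).  The loss is pluggable by name;
    ``prototypical_ce`` (softmax cross-entropy over negative squared
    prototype distances) is the default and currently the only shipped
    loss — ``corel`` is reserved as an extension slot.
    """

    epochs: int = 20
    episodes_per_epoch: int = 200
    learning_rate: float = 1e-3
    lr_decay: float = 0.95
    loss: str = "prototypical_ce"
    augmentation: AugmentationPolicy | None = None
    augment_targets: str = "both"
    embed_dim: int = 64
    init_seed: int = 0
    episode_seed: int = 1
    augment_seed: int = 2
    val_seed: int = 3
    val_episodes: int = 100
    # validation episodes see the same augmentation distribution as training
    # (frozen once into the bank), so checkpoint selection favors epochs that
    # are robust to the simulated variance rather than the raw base domain
    augment_validation: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.episodes_per_epoch < 1:
            raise ValueError("epochs and episodes_per_epoch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.loss == "corel":
            raise NotImplementedError(
                "the 'corel' loss slot is reserved; only its interface exists"
            )
        if self.loss != "prototypical_ce":
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingResult:
    embedder: ReferenceBackbone
    log: pd.DataFrame  # columns: epoch, train_loss, val_loss, lr
    best_epoch: int  # 1-based


def select_best_checkpoint(log: pd.DataFrame | Sequence[float]) -> int:
    """Epoch (1-based) with minimal validation loss; ties -> earliest."""
    if isinstance(log, pd.DataFrame):
        losses = log["val_loss"].to_numpy()
    else:
        losses = np.asarray(list(log), dtype=float)
    if losses.size == 0:
        raise ValueError("empty training log")
    return int(np.argmin(losses)) + 1


def train(
    ts: TrainingSet,
    val: TrainingSet,
    cfg: TrainingConfig,
    spec: EpisodeSpec,
    *,
    embedder: ReferenceBackbone | None = None,
    progress: Callable[[int, float, float], None] | None = None,
) -> TrainingResult:
    """Run the full episodic procedure and return the best-epoch embedder.

    Validation loss is computed after every epoch on a fixed seeded bank
    of ``cfg.val_episodes`` episodes drawn once from ``val`` (never
    augmented); the returned embedder carries the weights of the epoch
    with the lowest validation loss.
    """
    if embedder is None:
        embedder = build_reference_backbone(
            input_size=ts.patch_size, dim=cfg.embed_dim, init_seed=cfg.init_seed
        )
    opt = Adam(embedder.net.params(), lr=cfg.learning_rate)
    ep_rng = np.random.default_rng(np.random.SeedSequence([cfg.episode_seed & (2**63 - 1)]))
    aug_rng = np.random.default_rng(np.random.SeedSequence([cfg.augment_seed & (2**63 - 1)]))
    val_rng = np.random.default_rng(np.random.SeedSequence([cfg.val_seed & (2**63 - 1)]))
    val_bank = [sample_episode(val, spec, val_rng) for _ in range(cfg.val_episodes)]
    if cfg.augmentation is not None and cfg.augment_validation:
        for ep in val_bank:
            if cfg.augment_targets in ("both", "supports"):
                ep.support_x = augment_batch(ep.support_x, cfg.augmentation, val_rng)
            if cfg.augment_targets in ("both", "queries"):
                ep.query_x = augment_batch(ep.query_x, cfg.augmentation, val_rng)

    rows = []
    best: tuple[float, int, list[np.ndarray]] | None = None
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch - 1)
        train_losses = []
        for _ in range(cfg.episodes_per_epoch):
            episode = sample_episode(ts, spec, ep_rng)
            try:
                loss, grads = episode_loss(
                    episode,
                    embedder,
                    spec,
                    kmeans_seed=mix_seed(cfg.episode_seed, step),
                    augmentation=cfg.augmentation,
                    augment_rng=aug_rng,
                    augment_targets=cfg.augment_targets,
                    want_grads=True,
                )
            except TrainingDivergedError as exc:
                raise TrainingDivergedError(
                    f"epoch {epoch}, step {step}: {exc}"
                ) from exc
            opt.step(grads)
            train_losses.append(loss)
            step += 1
        val_loss = float(
            np.mean(
                [
                    episode_loss(ep, embedder, spec, kmeans_seed=mix_seed(cfg.val_seed, i))
                    for i, ep in enumerate(val_bank)
                ]
            )
        )
        train_loss = float(np.mean(train_losses))
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": opt.lr}
        )
        if best is None or val_loss < best[0]:
            best = (val_loss, epoch, embedder.state())
        if progress is not None:
            progress(epoch, train_loss, val_loss)

    log = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss", "lr"])
    best_epoch = select_best_checkpoint(log)
    assert best is not None and best[1] == best_epoch
    embedder.load_state(best[2])
    return TrainingResult(embedder=embedder, log=log, best_epoch=best_epoch)
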