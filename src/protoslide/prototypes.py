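"""Multi-prototype class representations and nearest-prototype classification.

Each class is represented by one or more latent-space prototypes — the
cluster centers of a k-means run over the class's support embeddings (or
one prototype per user annotation).  A query is assigned the class of its
nearest prototype under squared Euclidean distance.  The embedder stays
frozen throughout: swapping the prototype store adapts the classifier to
a new task without touching any network weight.

k-means is implemented here (k-means++ seeding, Lloyd iterations,
restarts, tolerance 1e-6 on center movement) because the multi-prototype
representation is the heart of the classifier and the episodic training
loop calls it thousands of times on tiny support sets; the test suite
cross-checks it against scikit-learn and a brute-force assignment
enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SupportSet",
    "PrototypeSet",
    "Classification",
    "kmeans_fit",
    "compute_prototypes_kmeans",
    "compute_prototypes_per_annotation",
    "classify",
    "classify_batch",
    "save_prototypes",
    "load_prototypes",
    "PrototypeStoreError",
    "PrototypeStoreFormatError",
    "PrototypeStoreVersionError",
    "PrototypeStoreFieldError",
    "EmptyClassError",
]

PROTOTYPE_STORE_VERSION = 1


class EmptyClassError(ValueError):
    """A declared class has no support vectors."""


class PrototypeStoreError(Exception):
    """Base class for prototype-store I/O failures."""


class PrototypeStoreFormatError(PrototypeStoreError):
    """The file is not well-formed JSON of the expected shape."""


class PrototypeStoreVersionError(PrototypeStoreError):
    """The store was written by an incompatible format version."""


class PrototypeStoreFieldError(PrototypeStoreError):
    """A required field (e.g. ``embedder_id``) is absent."""


@dataclass
class SupportSet:
    """Per-class support feature vectors, optionally tagged by annotation.

    ``vectors`` maps class label to an ``(n_c, d)`` array;
    ``annotation_ids`` (optional) gives one annotation id per vector, in
    the same order; ``source`` names the adaptation domain the supports
    came from.
    """

    vectors: dict[str, np.ndarray]
    annotation_ids: dict[str, list[str]] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        dims = set()
        for label, arr in self.vectors.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] == 0:
                raise EmptyClassError(f"class {label!r} has no support vectors")
            self.vectors[label] = arr
            dims.add(arr.shape[1])
        if len(dims) > 1:
            raise ValueError(f"support dimensions disagree: {sorted(dims)}")
        if self.annotation_ids is not None:
            for label, ids in self.annotation_ids.items():
                if label not in self.vectors:
                    raise ValueError(f"annotation ids for undeclared class {label!r}")
                if len(ids) != self.vectors[label].shape[0]:
                    raise ValueError(f"annotation id count mismatch for class {label!r}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(self.vectors)

    @classmethod
    def from_embedded(
        cls,
        features: np.ndarray,
        labels: Sequence[str],
        annotation_ids: Sequence[str] | None = None,
        source: str = "",
    ) -> "SupportSet":
        labels = np.asarray(labels, dtype=object)
        vectors = {str(c): np.asarray(features)[labels == c] for c in np.unique(labels)}
        ann = None
        if annotation_ids is not None:
            ids = np.asarray(annotation_ids, dtype=object)
            ann = {str(c): [str(a) for a in ids[labels == c]] for c in np.unique(labels)}
        return cls(vectors=vectors, annotation_ids=ann, source=source)


@dataclass
class PrototypeSet:
    """The portable 'adapted AI': per-class prototypes plus provenance."""

    embedder_id: str
    prototypes: dict[str, np.ndarray]  # label -> (k_c, d)
    k_used: dict[str, int] = field(default_factory=dict)
    n_supports: dict[str, int] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        dims = set()
        for label, arr in self.prototypes.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] == 0:
                raise ValueError(f"class {label!r} must have >= 1 prototype")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite prototype for class {label!r}")
            self.prototypes[label] = arr
            dims.add(arr.shape[1])
        if len(dims) > 1:
            raise ValueError(f"prototype dimensions disagree: {sorted(dims)}")
        self.k_used = {c: self.prototypes[c].shape[0] for c in self.prototypes} | dict(self.k_used)

    @property
    def dim(self) -> int:
        return next(iter(self.prototypes.values())).shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(self.prototypes)


@dataclass(frozen=True)
class Classification:
    """Hard label plus per-class distances and a softmax confidence.

    The confidence (softmax over negative squared distances) is a
    convenience addition for introspection; the decision is the hard
    nearest-prototype argmin.
    """

    label: str
    distances: dict[str, float]
    confidences: dict[str, float]


# ------------------------------------------------------------------ k-means


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 sampling)."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]), dtype=x.dtype)
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j:] = x[rng.integers(n, size=k - j)]
            break
        probs = d2 / total
        centers[j] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations until center movement < tol; empty clusters get the
    farthest point."""
    k = centers.shape[0]
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = x[assign == j]
            if members.shape[0] == 0:
                far = d2[np.arange(x.shape[0]), assign].argmax()
                new_centers[j] = x[far]
            else:
                new_centers[j] = members.mean(axis=0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    # final means so every returned center equals the mean of its members
    for j in range(k):
        members = x[assign == j]
        if members.shape[0]:
            centers[j] = members.mean(axis=0)
    inertia = float(d2[np.arange(x.shape[0]), assign].sum())
    return centers, assign, inertia


def kmeans_fit(
    x: np.ndarray,
    k: int,
    seed: int,
    *,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means with k-means++ init and restarts; returns (centers, labels, inertia).

    If fewer than ``k`` distinct points exist, ``k`` is reduced to that
    count (callers can detect this from the returned center count).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("x must be a non-empty (n, d) array")
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x, axis=0)
    k = min(k, distinct.shape[0])
    if k == 1:
        center = x.mean(axis=0, keepdims=True)
        inertia = float(((x - center) ** 2).sum())
        return center, np.zeros(x.shape[0], dtype=np.int64), inertia
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & (2**63 - 1)]))
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        centers = _kmeans_pp_init(x, k, rng)
        centers, assign, inertia = _lloyd(x, centers, tol, max_iter)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    return best


def compute_prototypes_kmeans(
    supports: SupportSet,
    k: int,
    seed: int,
    *,
    embedder_id: str = "",
    n_restarts: int = 10,
    tol: float = 1e-6,
) -> PrototypeSet:
    """Cluster each class's supports into (up to) ``k`` prototypes.

    Classes with fewer than ``k`` distinct support vectors get one
    prototype per distinct vector; the k actually used is recorded in the
    returned set's metadata.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    prototypes: dict[str, np.ndarray] = {}
    k_used: dict[str, int] = {}
    n_supports: dict[str, int] = {}
    for label in supports.classes:
        x = supports.vectors[label]
        centers, _, _ = kmeans_fit(x, k, mix_class_seed(seed, label), n_restarts=n_restarts, tol=tol)
        prototypes[label] = centers
        k_used[label] = centers.shape[0]
        n_supports[label] = x.shape[0]
    return PrototypeSet(
        embedder_id=embedder_id,
        prototypes=prototypes,
        k_used=k_used,
        n_supports=n_supports,
        source=supports.source,
    )


def mix_class_seed(seed: int, label: str) -> int:
    """Stable per-class k-means seed (class label folded into the seed)."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) & 0xFFFFFFFF
    return (int(seed) ^ h) & (2**31 - 1)


def compute_prototypes_per_annotation(
    supports: SupportSet, *, embedder_id: str = ""
) -> PrototypeSet:
    """One prototype per annotation: the mean of that annotation's supports."""
    if supports.annotation_ids is None:
        raise ValueError("supports carry no annotation ids")
    prototypes: dict[str, np.ndarray] = {}
    k_used: dict[str, int] = {}
    n_supports: dict[str, int] = {}
    for label in supports.classes:
        ids = np.asarray(supports.annotation_ids.get(label, []), dtype=object)
        if len(ids) != supports.vectors[label].shape[0]:
            raise ValueError(f"class {label!r} has supports without annotation ids")
        x = supports.vectors[label]
        centers = [x[ids == a].mean(axis=0) for a in sorted(set(ids))]
        prototypes[label] = np.stack(centers)
        k_used[label] = len(centers)
        n_supports[label] = x.shape[0]
    return PrototypeSet(
        embedder_id=embedder_id,
        prototypes=prototypes,
        k_used=k_used,
        n_supports=n_supports,
        source=supports.source,
    )


# ------------------------------------------------------------ classification


def _l2_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return x / np.where(norms == 0, 1.0, norms)


def class_distances(
    queries: np.ndarray, protos: PrototypeSet, *, l2_normalize: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Per-class minimum squared Euclidean distance for a (n, d) query stack.

    Returns ``(D, classes)`` with ``D[i, c] = min_p ||q_i - p||^2`` over
    class ``c``'s prototypes, classes in lexicographic order.  With
    ``l2_normalize`` queries and prototypes are projected to the unit
    sphere before the distance is taken (off by default: raw squared
    Euclidean distance in the latent space).
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if queries.shape[1] != protos.dim:
        raise ValueError(f"query dim {queries.shape[1]} != prototype dim {protos.dim}")
    if l2_normalize:
        queries = _l2_rows(queries)
    classes = protos.classes
    dists = np.empty((queries.shape[0], len(classes)))
    for j, label in enumerate(classes):
        p = protos.prototypes[label]
        if l2_normalize:
            p = _l2_rows(p)
        d2 = (
            (queries**2).sum(axis=1, keepdims=True)
            - 2.0 * queries @ p.T
            + (p**2).sum(axis=1)[None, :]
        )
        dists[:, j] = np.maximum(d2, 0.0).min(axis=1)
    return dists, classes


def classify_batch(
    queries: np.ndarray, protos: PrototypeSet, *, l2_normalize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-prototype decision; returns (labels, distance matrix).

    Ties on exactly equal class distances break toward the
    lexicographically first class label (argmin on the sorted class axis).
    """
    dists, classes = class_distances(queries, protos, l2_normalize=l2_normalize)
    idx = dists.argmin(axis=1)
    labels = np.asarray(classes, dtype=object)[idx]
    return labels, dists


def classify(
    query: np.ndarray, protos: PrototypeSet, *, l2_normalize: bool = False
) -> Classification:
    """Classify a single d-dimensional query vector."""
    dists, classes = class_distances(query, protos, l2_normalize=l2_normalize)
    d = dists[0]
    z = -d
    z = z - z.max()
    e = np.exp(z)
    conf = e / e.sum()
    label = classes[int(d.argmin())]
    return Classification(
        label=label,
        distances={c: float(v) for c, v in zip(classes, d)},
        confidences={c: float(v) for c, v in zip(classes, conf)},
    )


# -------------------------------------------------------------- persistence


def save_prototypes(protos: PrototypeSet, path: str | Path) -> None:
    """Serialize to JSON with full decimal precision (bit-exact round trip)."""
    if not protos.embedder_id:
        raise PrototypeStoreFieldError("cannot save a prototype set without an embedder_id")
    payload = {
        "version": PROTOTYPE_STORE_VERSION,
        "embedder_id": protos.embedder_id,
        "dim": protos.dim,
        "classes": [
            {
                "name": label,
                "k": protos.k_used.get(label, protos.prototypes[label].shape[0]),
                "n_supports": protos.n_supports.get(label, 0),
                "source": protos.source,
                "prototypes": [[repr(float(v)) for v in row] for row in protos.prototypes[label]],
            }
            for label in protos.classes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_prototypes(path: str | Path) -> PrototypeSet:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PrototypeStoreFormatError(f"malformed prototype store: {exc}") from exc
    if not isinstance(payload, dict) or "classes" not in payload:
        raise PrototypeStoreFormatError("prototype store missing 'classes'")
    version = payload.get("version")
    if version != PROTOTYPE_STORE_VERSION:
        raise PrototypeStoreVersionError(
            f"unsupported store version {version!r} (expected {PROTOTYPE_STORE_VERSION})"
        )
    embedder_id = payload.get("embedder_id")
    if not embedder_id:
        raise PrototypeStoreFieldError("prototype store missing embedder_id")
    prototypes: dict[str, np.ndarray] = {}
    k_used: dict[str, int] = {}
    n_supports: dict[str, int] = {}
    source = ""
    try:
        for entry in payload["classes"]:
            name = entry["name"]
            prototypes[name] = np.asarray(
                [[float(v) for v in row] for row in entry["prototypes"]], dtype=np.float64
            )
            k_used[name] = int(entry.get("k", prototypes[name].shape[0]))
            n_supports[name] = int(entry.get("n_supports", 0))
            source = entry.get("source", source)
    except (KeyError, TypeError, ValueError) as exc:
        raise PrototypeStoreFormatError(f"malformed class entry: {exc}") from exc
    protos = PrototypeSet(
        embedder_id=embedder_id,
        prototypes=prototypes,
        k_used=k_used,
        n_supports=n_supports,
        source=source,
    )
    if protos.dim != int(payload.get("dim", protos.dim)):
        raise PrototypeStoreFormatError("declared dim does not match prototype vectors")
    return protos
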