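"""The frozen feature-extraction contract and a desk-scale reference CNN.

A few-shot classifier is the pair (frozen embedder f_theta, prototype
set).  The embedder maps an 8-bit patch to a d-dimensional feature vector
and is never updated when prototypes are (re)built — adaptation to a new
task touches only the prototypes.  Any object satisfying :class:`Embedder`
can be plugged in; the shipped :class:`ReferenceBackbone` is a small
4-conv-block network (strided convs, global average pooling, dense
projection to ``d``) trainable on one CPU, standing in for the
ImageNet-scale encoders used on clinical data.

Inputs are normalized to [0, 1] floats at the embedder boundary
(``input_norm="standardize"`` additionally applies per-patch channel
standardization, a color-constancy step that trades the absolute stain
intensity signal for invariance to gain/offset shifts; the default keeps
the absolute signal).  The weight hash (sha256 over all parameter bytes)
identifies a trained state and is recorded in every prototype store for
compatibility checking.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .nn import Conv2d, Dense, GlobalAvgPool, ReLU, Sequential
from .patches import PatchDataset, RgbPatch

__all__ = [
    "Embedder",
    "ReferenceBackbone",
    "EmbeddedDataset",
    "build_reference_backbone",
    "embed_batch",
]


@runtime_checkable
class Embedder(Protocol):
    """Frozen map from uint8 patches to d-dimensional feature vectors."""

    dim: int
    input_size: int

    @property
    def embedder_id(self) -> str: ...

    def embed(self, patches: np.ndarray) -> np.ndarray: ...

    def weight_hash(self) -> str: ...


@dataclass
class EmbeddedDataset:
    """Feature vectors with class/domain labels and patch ids."""

    features: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,) str
    domains: np.ndarray  # (N,) str
    patch_ids: np.ndarray  # (N,) str

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.domains) == len(self.patch_ids) == n):
            raise ValueError("column lengths disagree")

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def by_class(self) -> dict[str, np.ndarray]:
        return {c: self.features[self.labels == c] for c in np.unique(self.labels)}


class ReferenceBackbone:
    """Small seeded CNN: 4 strided conv blocks -> GAP -> dense projection.

    Architecture (channels-last, input ``s x s x 3`` in [0, 1]), with the
    default ``conv_spec`` of (kernel, stride, channels) triples:

    ====== ============================ ==========
    block  op                           output
    ====== ============================ ==========
    1      conv 7x7 /4 pad 3, ReLU      s/4  x 12
    2      conv 3x3 /2 pad 1, ReLU      s/8  x 24
    3      conv 3x3 /2 pad 1, ReLU      s/16 x 32
    4      conv 3x3 /1 pad 1, ReLU      s/16 x 48
    5      global average pool          48
    6      dense 48 -> d                d
    ====== ============================ ==========

    The aggressive first-layer downsampling keeps one CPU training step
    cheap.  The architecture string and weight hash make ``embedder_id``
    stable across processes for identical seeds/weights.
    """

    DEFAULT_CONV_SPEC = ((7, 4, 12), (3, 2, 24), (3, 2, 32), (3, 1, 48))

    def __init__(
        self,
        input_size: int = 64,
        dim: int = 64,
        init_seed: int = 0,
        *,
        conv_spec: tuple[tuple[int, int, int], ...] = DEFAULT_CONV_SPEC,
        input_norm: str = "unit",
        dtype: np.dtype = np.float32,
    ):
        if input_size < 16:
            raise ValueError("input_size must be >= 16")
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.input_size = int(input_size)
        self.dim = int(dim)
        self.init_seed = int(init_seed)
        self.conv_spec = tuple((int(k), int(s), int(c)) for k, s, c in conv_spec)
        if input_norm not in ("unit", "standardize"):
            raise ValueError("input_norm must be 'unit' or 'standardize'")
        self.input_norm = input_norm
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(np.random.SeedSequence([init_seed & (2**63 - 1)]))
        layers: list = []
        c_in = 3
        for i, (kernel, stride, c_out) in enumerate(self.conv_spec):
            layers.append(
                Conv2d(
                    c_in,
                    c_out,
                    kernel,
                    stride=stride,
                    pad=kernel // 2,
                    rng=rng,
                    dtype=self.dtype,
                    compute_dx=i > 0,
                )
            )
            layers.append(ReLU())
            c_in = c_out
        layers.append(GlobalAvgPool())
        layers.append(Dense(c_in, dim, rng=rng, dtype=self.dtype))
        self.net = Sequential(layers)

    # ------------------------------------------------------------- identity

    @property
    def architecture(self) -> str:
        c = "-".join(f"{k}x{k}s{s}c{ch}" for k, s, ch in self.conv_spec)
        norm = "std" if self.input_norm == "standardize" else "unit"
        return f"refnet/{self.input_size}px/{norm}/{c}/d{self.dim}"

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.net.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    @property
    def embedder_id(self) -> str:
        return f"{self.architecture}#{self.weight_hash()[:16]}"

    # ------------------------------------------------------------ inference

    def _to_float(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim != 4 or patches.shape[3] != 3:
            raise ValueError(f"expected (B, H, W, 3), got {patches.shape}")
        if patches.shape[1] != self.input_size or patches.shape[2] != self.input_size:
            raise ValueError(
                f"patch size {patches.shape[1]}x{patches.shape[2]} does not match "
                f"embedder input size {self.input_size} (no silent resize)"
            )
        if patches.dtype == np.uint8:
            x = patches.astype(self.dtype) / np.asarray(255.0, dtype=self.dtype)
        else:
            x = patches.astype(self.dtype, copy=False)
        if self.input_norm == "standardize":
            # per-patch per-channel standardization: a color-constancy step
            # that removes gain/offset shifts exactly and most of a global
            # saturation shift, at the cost of absolute stain intensity
            mean = x.mean(axis=(1, 2), keepdims=True)
            std = x.std(axis=(1, 2), keepdims=True)
            x = (x - mean) / (std + np.asarray(1e-4, dtype=self.dtype))
        return x

    def forward(self, patches: np.ndarray, *, cache: bool = False) -> np.ndarray:
        """Float forward pass; ``cache=True`` retains activations for backward."""
        return self.net.forward(self._to_float(patches), cache=cache)

    def embed(self, patches: np.ndarray, *, batch_size: int = 512) -> np.ndarray:
        """Embed a (B, s, s, 3) uint8 stack into (B, d) feature vectors."""
        patches = np.asarray(patches)
        if patches.shape[0] == 0:
            return np.zeros((0, self.dim), dtype=self.dtype)
        chunks = [
            self.forward(patches[i : i + batch_size])
            for i in range(0, patches.shape[0], batch_size)
        ]
        out = np.concatenate(chunks, axis=0)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("embedder produced non-finite features")
        return out

    # ---------------------------------------------------------- persistence

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.net.params()]

    def load_state(self, values: Sequence[np.ndarray]) -> None:
        self.net.set_params(list(values))

    def save(self, path: str | Path) -> None:
        meta = dict(
            input_size=self.input_size,
            dim=self.dim,
            init_seed=self.init_seed,
            conv_spec=np.asarray(self.conv_spec),
            input_norm=self.input_norm,
        )
        arrays = {f"param_{i}": p for i, p in enumerate(self.net.params())}
        np.savez(path, **meta, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceBackbone":
        with np.load(path) as data:
            model = cls(
                input_size=int(data["input_size"]),
                dim=int(data["dim"]),
                init_seed=int(data["init_seed"]),
                conv_spec=tuple(tuple(int(v) for v in row) for row in data["conv_spec"]),
                input_norm=str(data["input_norm"]) if "input_norm" in data else "unit",
            )
            n = len(model.net.params())
            model.load_state([data[f"param_{i}"] for i in range(n)])
        return model


def build_reference_backbone(
    input_size: int = 64, dim: int = 64, init_seed: int = 0, **kwargs
) -> ReferenceBackbone:
    """Construct the seeded reference backbone (see :class:`ReferenceBackbone`)."""
    return ReferenceBackbone(input_size=input_size, dim=dim, init_seed=init_seed, **kwargs)


def embed_batch(
    embedder: ReferenceBackbone,
    patches: PatchDataset | Sequence[RgbPatch],
) -> EmbeddedDataset:
    """Embed labeled patches, preserving order and provenance."""
    items = list(patches)
    if not items:
        return EmbeddedDataset(
            features=np.zeros((0, embedder.dim), dtype=np.float32),
            labels=np.asarray([], dtype=object),
            domains=np.asarray([], dtype=object),
            patch_ids=np.asarray([], dtype=object),
        )
    stack = np.stack([p.pixels for p in items])
    features = embedder.embed(stack)
    return EmbeddedDataset(
        features=features,
        labels=np.asarray([p.label for p in items], dtype=object),
        domains=np.asarray([p.domain for p in items], dtype=object),
        patch_ids=np.asarray([p.patch_id for p in items], dtype=object),
    )
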