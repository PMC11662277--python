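"""End-to-end experiment drivers on the synthetic multi-scanner benchmark.

Three designs are provided, mirroring how robustness and adaptability of
prototypical few-shot classifiers are studied on clinical data, executed
at desk scale on synthetic H&E-like patches:

* :func:`run_robustness_experiment` — train the embedder on the base
  domain only, with and without augmentation, over several seeds; build
  prototypes from the base-domain adaptation split; evaluate on every
  domain's test split.  The signature result is that augmentation
  preserves in-domain accuracy while strongly lifting shifted-domain
  accuracy.
* :func:`run_prototype_source_experiment` — keep the augmented embedders
  fixed and swap in prototypes built from each domain's adaptation split;
  report the accuracy matrix and the mean absolute deviation from the
  base-domain-prototype row.
* :func:`run_adaptation_experiment` — freeze a trained embedder and adapt
  it to a disjoint task (novel super-classes composed of subclasses, a
  few annotations per subclass) purely by exchanging prototypes; the
  weight hash is asserted unchanged.

Dataset sizes, episode geometry and schedules live in
:class:`BenchmarkConfig`; the defaults define the package's standard
benchmark conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy
from .embedding import ReferenceBackbone, embed_batch
from .evaluation import EvaluationReport, evaluate
from .patches import PatchDataset
from .prototypes import (
    PrototypeSet,
    SupportSet,
    classify_batch,
    compute_prototypes_kmeans,
)
from .synthetic import (
    IDENTITY_SCANNER,
    SyntheticDatasetSpec,
    TissueClassSpec,
    default_scanner_profiles,
    default_tissue_classes,
    generate_dataset,
    generate_patch,
    mix_seed,
)
from .training import EpisodeSpec, TrainingConfig, TrainingResult, TrainingSet, train

__all__ = [
    "BenchmarkConfig",
    "SplitSizes",
    "split_dataset",
    "prepare_benchmark_data",
    "train_benchmark_models",
    "build_domain_prototypes",
    "evaluate_model",
    "run_robustness_experiment",
    "run_prototype_source_experiment",
    "run_adaptation_experiment",
    "adaptation_task_classes",
    "RobustnessResult",
    "PrototypeSourceResult",
    "AdaptationResult",
]

PROTOTYPE_SAMPLING_SEED = 777  # prototype draws fixed across training seeds


@dataclass(frozen=True)
class SplitSizes:
    """Per-(class, domain) patch counts of the four disjoint splits."""

    train: int = 90
    val: int = 20
    adapt: int = 20
    test: int = 20

    @property
    def total(self) -> int:
        return self.train + self.val + self.adapt + self.test


@dataclass
class BenchmarkConfig:
    """Conditions of the synthetic domain-generalization benchmark.

    Four tissue classes under one base scanner plus three shifted
    scanners, 150 patches per class and domain at 64 px; the embedder is
    trained on the base domain only (3-way 10-shot episodes, 5 queries,
    k_ep = 3) for 30 epochs of 200 episodes; prototypes use k = 3 with
    up to 1000 supports per class (all available when fewer).
    """

    classes: tuple[TissueClassSpec, ...] = field(default_factory=default_tissue_classes)
    scanners: tuple = field(default_factory=default_scanner_profiles)
    patches_per_class_per_scanner: int = 150
    patch_size: int = 64
    dataset_seed: int = 20240606
    splits: SplitSizes = field(default_factory=SplitSizes)
    episode: EpisodeSpec = field(default_factory=lambda: EpisodeSpec(nc=3, ns=10, nq=5, k_ep=3))
    epochs: int = 30
    episodes_per_epoch: int = 200
    learning_rate: float = 2e-3
    lr_decay: float = 0.95
    embed_dim: int = 64
    val_episodes: int = 100
    k_prototypes: int = 3
    supports_per_class: int = 1000
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.splits.total != self.patches_per_class_per_scanner:
            raise ValueError("split sizes must sum to patches_per_class_per_scanner")

    @property
    def base_domain(self) -> str:
        return self.scanners[0].name

    @property
    def shifted_domains(self) -> list[str]:
        return [s.name for s in self.scanners[1:]]

    def dataset_spec(self) -> SyntheticDatasetSpec:
        return SyntheticDatasetSpec(
            classes=tuple(self.classes),
            scanners=tuple(self.scanners),
            patches_per_class_per_scanner=self.patches_per_class_per_scanner,
            patch_size=self.patch_size,
            master_seed=self.dataset_seed,
        )

    def training_config(self, seed: int, augmented: bool) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs,
            episodes_per_epoch=self.episodes_per_epoch,
            learning_rate=self.learning_rate,
            lr_decay=self.lr_decay,
            augmentation=AugmentationPolicy.default() if augmented else None,
            embed_dim=self.embed_dim,
            init_seed=mix_seed(seed, 11),
            episode_seed=mix_seed(seed, 13),
            augment_seed=mix_seed(seed, 17),
            val_seed=mix_seed(seed, 19),
            val_episodes=self.val_episodes,
        )


def split_dataset(ds: PatchDataset, sizes: SplitSizes) -> dict[str, PatchDataset]:
    """Split per (domain, class) group by patch index: train|val|adapt|test.

    Within each group the manifest order (generation order) is used, so
    splits are deterministic and disjoint.
    """
    manifest = ds.manifest
    order = np.zeros(len(ds), dtype=np.int64)
    for _, grp in manifest.groupby(["domain", "class"], sort=False):
        order[grp.index.to_numpy()] = np.arange(len(grp))
    bounds = {
        "train": (0, sizes.train),
        "val": (sizes.train, sizes.train + sizes.val),
        "adapt": (sizes.train + sizes.val, sizes.train + sizes.val + sizes.adapt),
        "test": (sizes.train + sizes.val + sizes.adapt, sizes.total),
    }
    return {
        name: ds.subset((order >= lo) & (order < hi)) for name, (lo, hi) in bounds.items()
    }


def prepare_benchmark_data(cfg: BenchmarkConfig) -> dict[str, PatchDataset]:
    """Generate the benchmark dataset and split it."""
    dataset = generate_dataset(cfg.dataset_spec())
    return split_dataset(dataset, cfg.splits)


def train_benchmark_models(
    cfg: BenchmarkConfig,
    splits: Mapping[str, PatchDataset],
    *,
    variants: Sequence[bool] = (True, False),
    seeds: Sequence[int] | None = None,
    progress=None,
) -> dict[tuple[bool, int], TrainingResult]:
    """Train (augmented?, seed) embedder variants on the base-domain split."""
    seeds = list(cfg.seeds if seeds is None else seeds)
    base = cfg.base_domain
    ts = TrainingSet.from_dataset(splits["train"].filter(domain=base))
    val = TrainingSet.from_dataset(splits["val"].filter(domain=base))
    models: dict[tuple[bool, int], TrainingResult] = {}
    for augmented in variants:
        for seed in seeds:
            tc = cfg.training_config(seed, augmented)
            models[(augmented, seed)] = train(
                ts, val, tc, cfg.episode, progress=progress
            )
    return models


def build_domain_prototypes(
    embedder: ReferenceBackbone,
    adapt_split: PatchDataset,
    domain: str,
    *,
    k: int,
    supports_per_class: int,
    sampling_seed: int = PROTOTYPE_SAMPLING_SEED,
) -> PrototypeSet:
    """k-means prototypes from one domain's adaptation split.

    Supports are a seeded uniform sample without replacement of up to
    ``supports_per_class`` patches per class (all available when fewer).
    """
    subset = adapt_split.filter(domain=domain)
    rng = np.random.default_rng(np.random.SeedSequence([sampling_seed]))
    keep = np.zeros(len(subset), dtype=bool)
    labels = subset.labels()
    for c in subset.classes:
        rows = np.flatnonzero(labels == c)
        take = rows if len(rows) <= supports_per_class else rng.choice(
            rows, size=supports_per_class, replace=False
        )
        keep[take] = True
    sample = subset.subset(keep)
    emb = embed_batch(embedder, sample)
    supports = SupportSet.from_embedded(emb.features, emb.labels, source=domain)
    return compute_prototypes_kmeans(
        supports, k, mix_seed(sampling_seed, 1), embedder_id=embedder.embedder_id
    )


def evaluate_model(
    embedder: ReferenceBackbone,
    protos: PrototypeSet,
    test_split: PatchDataset,
    domain: str,
) -> float:
    """Nearest-prototype accuracy on one domain's test split."""
    subset = test_split.filter(domain=domain)
    emb = embed_batch(embedder, subset)
    pred, _ = classify_batch(emb.features, protos)
    return float(np.mean(pred == emb.labels))


# ------------------------------------------------------------- experiments


@dataclass
class RobustnessResult:
    raw: pd.DataFrame  # domain, variant, seed, accuracy
    table: pd.DataFrame  # per (domain, variant): mean, sd
    base_domain: str

    def mean_accuracy(self, *, domain: str, augmented: bool) -> float:
        rows = self.raw[(self.raw["domain"] == domain) & (self.raw["augmented"] == augmented)]
        return float(rows["accuracy"].mean())

    def shifted_domain_gap(self, shifted: Sequence[str]) -> float:
        """Mean over shifted domains of (augmented - non-augmented) accuracy."""
        gaps = [
            self.mean_accuracy(domain=d, augmented=True)
            - self.mean_accuracy(domain=d, augmented=False)
            for d in shifted
        ]
        return float(np.mean(gaps))


def run_robustness_experiment(
    cfg: BenchmarkConfig,
    *,
    splits: Mapping[str, PatchDataset] | None = None,
    models: Mapping[tuple[bool, int], TrainingResult] | None = None,
    progress=None,
) -> tuple[RobustnessResult, dict[tuple[bool, int], TrainingResult], dict[str, PatchDataset]]:
    """Augmented-vs-plain training evaluated across all scanner domains.

    Returns the result plus the trained models and splits so follow-up
    experiments can reuse the (expensive) embedders.
    """
    if splits is None:
        splits = prepare_benchmark_data(cfg)
    if models is None:
        models = train_benchmark_models(cfg, splits, progress=progress)
    rows = []
    domains = [s.name for s in cfg.scanners]
    for (augmented, seed), result in models.items():
        protos = build_domain_prototypes(
            result.embedder,
            splits["adapt"],
            cfg.base_domain,
            k=cfg.k_prototypes,
            supports_per_class=cfg.supports_per_class,
        )
        for domain in domains:
            acc = evaluate_model(result.embedder, protos, splits["test"], domain)
            rows.append(
                {"domain": domain, "augmented": augmented, "seed": seed, "accuracy": acc}
            )
    raw = pd.DataFrame(rows)
    table = (
        raw.groupby(["domain", "augmented"])["accuracy"].agg(["mean", "std"]).reset_index()
    )
    return RobustnessResult(raw=raw, table=table, base_domain=cfg.base_domain), dict(models), dict(splits)


@dataclass
class PrototypeSourceResult:
    matrix: pd.DataFrame  # index: source domain, columns: eval domain (seed-mean)
    mean_abs_deviation: float  # vs the base-domain-prototype row
    base_domain: str


def run_prototype_source_experiment(
    cfg: BenchmarkConfig,
    models: Mapping[tuple[bool, int], TrainingResult],
    splits: Mapping[str, PatchDataset],
) -> PrototypeSourceResult:
    """Swap prototype origin across domains, embedder fixed (augmented runs)."""
    domains = [s.name for s in cfg.scanners]
    aug_models = {s: r for (a, s), r in models.items() if a}
    if not aug_models:
        raise ValueError("prototype-source experiment needs augmented models")
    acc = np.zeros((len(domains), len(domains)))
    for _, result in aug_models.items():
        for i, source in enumerate(domains):
            protos = build_domain_prototypes(
                result.embedder,
                splits["adapt"],
                source,
                k=cfg.k_prototypes,
                supports_per_class=cfg.supports_per_class,
            )
            for j, eval_domain in enumerate(domains):
                acc[i, j] += evaluate_model(
                    result.embedder, protos, splits["test"], eval_domain
                )
    acc /= len(aug_models)
    matrix = pd.DataFrame(acc, index=pd.Index(domains, name="source"), columns=domains)
    base_row = matrix.loc[cfg.base_domain]
    deviations = (matrix.drop(index=cfg.base_domain) - base_row).abs().to_numpy()
    return PrototypeSourceResult(
        matrix=matrix,
        mean_abs_deviation=float(deviations.mean()),
        base_domain=cfg.base_domain,
    )


# ------------------------------------------------- adaptation to a new task


def adaptation_task_classes() -> dict[str, tuple[TissueClassSpec, TissueClassSpec]]:
    """Novel super-classes (disjoint from the benchmark classes), each
    composed of two generatively distinct subclasses.

    The trio emulates the normal/tumor/necrosis regrouping of a second
    tumor entity: 'necrosis' is pale and fragmented, 'muscle' eosin-rich
    and nearly anuclear, 'lesion' dense and hematoxylin-heavy.
    """
    return {
        "lesion": (
            TissueClassSpec("lesion_solid", 55.0, 3.8, 0.7, 1.00, 0.30, texture_seed_offset=21),
            TissueClassSpec("lesion_diffuse", 30.0, 2.4, 0.5, 0.90, 0.40, texture_seed_offset=22),
        ),
        "muscle": (
            TissueClassSpec("muscle_smooth", 6.0, 3.0, 0.6, 0.30, 0.95, texture_seed_offset=23),
            TissueClassSpec("muscle_skeletal", 12.0, 3.5, 0.7, 0.40, 0.75, texture_seed_offset=24),
        ),
        "necrosis": (
            TissueClassSpec("necrosis_debris", 25.0, 1.2, 0.25, 0.40, 0.30, texture_seed_offset=25),
            TissueClassSpec("necrosis_ghost", 2.0, 3.0, 0.8, 0.12, 0.30, texture_seed_offset=26),
        ),
    }


@dataclass
class AdaptationResult:
    report: EvaluationReport
    prototypes: PrototypeSet
    weight_hash_before: str
    weight_hash_after: str

    @property
    def weights_unchanged(self) -> bool:
        return self.weight_hash_before == self.weight_hash_after


def run_adaptation_experiment(
    embedder: ReferenceBackbone,
    *,
    task_classes: Mapping[str, tuple[TissueClassSpec, ...]] | None = None,
    patch_size: int = 64,
    k: int = 6,
    annotations_per_subclass: int = 3,
    supports_per_annotation: int = 10,
    test_per_subclass: int = 30,
    seed: int = 515151,
) -> AdaptationResult:
    """Adapt a frozen embedder to a novel task by exchanging prototypes.

    Per subclass, ``annotations_per_subclass`` annotation groups of
    ``supports_per_annotation`` patches form the adaptation set; pooled
    per super-class k-means (default k = 6) builds the prototypes.  The
    embedder weight hash is recorded before and after so callers can
    assert no weight changed.
    """
    if task_classes is None:
        task_classes = adaptation_task_classes()
    hash_before = embedder.weight_hash()

    support_vecs: list[np.ndarray] = []
    support_labels: list[str] = []
    support_ann: list[str] = []
    test_patches: list = []
    sub_counter = 0
    for super_label in sorted(task_classes):
        for sub in task_classes[super_label]:
            for ann in range(annotations_per_subclass):
                patches = [
                    generate_patch(
                        sub, IDENTITY_SCANNER, patch_size, mix_seed(seed, sub_counter, ann, i)
                    )
                    for i in range(supports_per_annotation)
                ]
                stack = np.stack([p.pixels for p in patches])
                support_vecs.append(embedder.embed(stack))
                support_labels.extend([super_label] * len(patches))
                support_ann.extend([f"{sub.name}-ann{ann}"] * len(patches))
            for i in range(test_per_subclass):
                p = generate_patch(
                    sub, IDENTITY_SCANNER, patch_size, mix_seed(seed, sub_counter, 999, i)
                )
                p.label = super_label
                test_patches.append(p)
            sub_counter += 1

    supports = SupportSet.from_embedded(
        np.concatenate(support_vecs),
        support_labels,
        annotation_ids=support_ann,
        source="task-b-adaptation",
    )
    protos = compute_prototypes_kmeans(
        supports, k, mix_seed(seed, 7), embedder_id=embedder.embedder_id
    )

    emb = embed_batch(embedder, test_patches)
    pred, _ = classify_batch(emb.features, protos)
    report = evaluate(
        [(t, p, d) for t, p, d in zip(emb.labels, pred, emb.patch_ids)],
        labels=sorted(task_classes),
        seed=mix_seed(seed, 9) & (2**31 - 1),
    )
    return AdaptationResult(
        report=report,
        prototypes=protos,
        weight_hash_before=hash_before,
        weight_hash_after=embedder.weight_hash(),
    )
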