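# protoslide

Prototypical few-shot classification of histopathology tissue patches,
with stain-specific data augmentation for robustness against scanner
domain shift, and a prototype-swap workflow for adapting a trained
classifier to a new task **without retraining any network weights**.

## Who this is for

Digital-pathology tool builders and method researchers who want a small,
fully inspectable implementation of the "interactive AI authoring"
recipe: train a patch embedder once, then let a non-technical user create
or adapt classifiers purely by annotating a few example regions. Because
no real multi-scanner H&E dataset can ship with a package, everything is
exercisable end to end on a built-in synthetic data generator that
renders H&E-like patches under simulated scanner domains (hue/saturation
drift, white-balance gain/offset, defocus blur, sensor noise).

## The method

A frozen CNN embedder `f_θ` maps a patch to `ℝ^d`. Each class `c` is
represented by prototypes `{p_c1 … p_ck}` — k-means centers of the
class's support embeddings (or one prototype per annotation). A query
`q` gets the class of its nearest prototype under squared Euclidean
distance:

    ŷ(q) = argmin_c min_j ‖f_θ(q) − p_cj‖²

Training is episodic (Nc-way Ns-shot): each step samples Nc classes with
Ns supports and Nq queries, builds k_ep prototypes per class from the
supports, and minimizes softmax cross-entropy over the negative squared
distances of the queries. During training, four stain-specific
augmentations fire stochastically (HED color-deconvolution jitter, hue
jitter, saturation jitter, Gaussian blur — the color ones with p = 0.5,
blur with p = 0.3), which is what makes the embedding robust to scanner
shift. Adaptation to a new task = swap the prototype JSON; the embedder
hash is asserted unchanged.

See `docs/methods.md` for the full model description, numerical
conventions, and the synthetic benchmark design.

## Worked example

```python
import numpy as np
from protoslide import (
    AugmentationPolicy, EpisodeSpec, TrainingConfig, TrainingSet,
    SyntheticDatasetSpec, default_scanner_profiles, default_tissue_classes,
    generate_dataset, train,
)
from protoslide.experiments import build_domain_prototypes, evaluate_model
from protoslide.experiments import BenchmarkConfig, SplitSizes, split_dataset

# 4 tissue classes x 4 scanner domains, 64-px patches, fully seeded
spec = SyntheticDatasetSpec(
    classes=default_tissue_classes(),
    scanners=default_scanner_profiles(),
    patches_per_class_per_scanner=150,
    patch_size=64,
    master_seed=20240606,
)
splits = split_dataset(generate_dataset(spec), SplitSizes(90, 20, 20, 20))

# train on the base domain only, with stain augmentation
cfg = BenchmarkConfig()
result = train(
    TrainingSet.from_dataset(splits["train"].filter(domain="scanner_a")),
    TrainingSet.from_dataset(splits["val"].filter(domain="scanner_a")),
    cfg.training_config(seed=0, augmented=True),
    EpisodeSpec(nc=3, ns=10, nq=5, k_ep=3),
)
print("best epoch:", result.best_epoch)

# build k=3 prototypes from the base-domain adaptation split, evaluate everywhere
protos = build_domain_prototypes(
    result.embedder, splits["adapt"], "scanner_a", k=3, supports_per_class=1000
)
for domain in ("scanner_a", "scanner_b", "scanner_c", "scanner_d"):
    acc = evaluate_model(result.embedder, protos, splits["test"], domain)
    print(f"{domain}: {acc:.3f}")
```

Output of this exact script (seed 0; ~3 minutes on one CPU):

```
best epoch: 7
scanner_a: 1.000
scanner_b: 0.925
scanner_c: 0.738
scanner_d: 0.988
```

The embedder never saw scanners b–d, yet accuracy stays far above the
plain-training baseline — the same model trained *without* augmentation
scores 1.000 on scanner_a but only 0.250–0.700 on the shifted domains
(averaged over three seeds the augmented model reaches 0.78–0.98 per
shifted domain against 0.25–0.62 without augmentation). scanner_c, the
compound shift (hue −12°, saturation ×0.72, offset, blur, noise), is the
hardest domain at this training scale.

## Command line

```bash
protoslide simulate --out-dir data/ --patches 150 --seed 0
protoslide train --dataset data/ --config run.yaml --out-dir run/
protoslide build-prototypes --dataset data/ --embedder run/embedder.npz \
    --domain scanner_a --k 3 --out protos.json
protoslide classify patch.png --embedder run/embedder.npz --prototypes protos.json
protoslide evaluate --dataset data/ --embedder run/embedder.npz \
    --prototypes protos.json --out-dir eval/
protoslide experiment robustness --out-dir exp/       # the full benchmark
protoslide extract-patches --slide slide.png --annotations regions.geojson \
    --out-dir patches/                                # 85%-overlap rule
```

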