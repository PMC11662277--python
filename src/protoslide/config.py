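"""YAML run configuration: episode geometry, training schedule, augmentation.

Example::

    episode: {nc: 3, ns: 10, nq: 5, k_ep: 3}
    training:
      epochs: 30
      episodes_per_epoch: 200
      learning_rate: 1.0e-3
      lr_decay: 0.95
    augmentation:
      - {name: hed_jitter, p: 0.5, params: {alpha_sigma: 0.05, beta_sigma: 0.05}}
      - {name: hue_jitter, p: 0.5, params: {max_shift_deg: 20.0}}
      - {name: saturation_jitter, p: 0.5, params: {sigma: 0.25}}
      - {name: gaussian_blur, p: 0.3, params: {sigma_max: 2.0}}

An absent ``augmentation:`` section trains without augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .augment import AugmentationPolicy
from .training import EpisodeSpec, TrainingConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    episode: EpisodeSpec
    training: TrainingConfig


def load_run_config(path: str | Path, *, seed: int | None = None) -> RunConfig:
    """Parse a YAML run config; ``seed`` overrides the file's seeds."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ep = raw.get("episode", {})
    episode = EpisodeSpec(
        nc=int(ep.get("nc", 3)),
        ns=int(ep.get("ns", 10)),
        nq=int(ep.get("nq", 5)),
        k_ep=int(ep.get("k_ep", 3)),
    )
    tr = dict(raw.get("training", {}))
    policy = None
    if "augmentation" in raw and raw["augmentation"]:
        policy = AugmentationPolicy.from_config(raw["augmentation"])
    if seed is not None:
        tr.setdefault("init_seed", seed)
        tr.setdefault("episode_seed", seed + 1)
        tr.setdefault("augment_seed", seed + 2)
        tr.setdefault("val_seed", seed + 3)
    training = TrainingConfig(augmentation=policy, **{k: v for k, v in tr.items()})
    return RunConfig(episode=episode, training=training)
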