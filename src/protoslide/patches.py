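"""Patch containers: a single RGB tile with provenance and datasets thereof.

A patch dataset pairs an in-memory stack of 8-bit sRGB tiles with a pandas
manifest (one row per patch).  On disk a dataset is laid out as
``root/<domain>/<class>/<patch_id>.png`` plus ``manifest.csv`` with columns
``patch_id, domain, class, x, y, seed`` — the format produced both by the
synthetic generator and by annotation-driven patch extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["RgbPatch", "PatchDataset", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["patch_id", "domain", "class", "x", "y", "seed"]


def _validate_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"patch must be (H, W, 3), got {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("patch must have positive height and width")
    if pixels.dtype != np.uint8:
        if np.issubdtype(pixels.dtype, np.floating) or np.issubdtype(pixels.dtype, np.integer):
            if pixels.min() < 0 or pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            pixels = np.rint(pixels).astype(np.uint8)
        else:
            raise ValueError(f"unsupported pixel dtype {pixels.dtype}")
    return pixels


@dataclass
class RgbPatch:
    """An 8-bit sRGB image tile with optional provenance metadata."""

    pixels: np.ndarray
    patch_id: str = ""
    label: str | None = None
    domain: str | None = None
    x: int = 0
    y: int = 0
    seed: int = 0
    annotation_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def as_pixel_array(patch: "RgbPatch | np.ndarray") -> np.ndarray:
    """Accept either a bare uint8 array or an :class:`RgbPatch`."""
    if isinstance(patch, RgbPatch):
        return patch.pixels
    return _validate_pixels(patch)


class PatchDataset:
    """Labeled patches plus their manifest, in memory or on disk."""

    def __init__(self, patches: Sequence[RgbPatch], manifest: pd.DataFrame | None = None):
        self._patches = list(patches)
        if manifest is None:
            manifest = pd.DataFrame(
                [
                    {
                        "patch_id": p.patch_id,
                        "domain": p.domain,
                        "class": p.label,
                        "x": p.x,
                        "y": p.y,
                        "seed": p.seed,
                    }
                    for p in self._patches
                ],
                columns=MANIFEST_COLUMNS,
            )
        if list(manifest.columns) != MANIFEST_COLUMNS:
            raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
        if len(manifest) != len(self._patches):
            raise ValueError("manifest length does not match number of patches")
        self.manifest = manifest.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self._patches)

    def __iter__(self) -> Iterator[RgbPatch]:
        return iter(self._patches)

    def __getitem__(self, i: int) -> RgbPatch:
        return self._patches[i]

    @property
    def classes(self) -> list[str]:
        return sorted(self.manifest["class"].unique())

    @property
    def domains(self) -> list[str]:
        return sorted(self.manifest["domain"].unique())

    def subset(self, mask: np.ndarray) -> "PatchDataset":
        mask = np.asarray(mask, dtype=bool)
        patches = [p for p, m in zip(self._patches, mask) if m]
        return PatchDataset(patches, self.manifest[mask].reset_index(drop=True))

    def filter(self, *, domain: str | None = None, label: str | None = None) -> "PatchDataset":
        mask = np.ones(len(self), dtype=bool)
        if domain is not None:
            mask &= (self.manifest["domain"] == domain).to_numpy()
        if label is not None:
            mask &= (self.manifest["class"] == label).to_numpy()
        return self.subset(mask)

    def pixel_stack(self) -> np.ndarray:
        """All patches as one ``(N, H, W, 3)`` uint8 array (uniform size required)."""
        if not self._patches:
            return np.zeros((0, 0, 0, 3), dtype=np.uint8)
        sizes = {p.pixels.shape for p in self._patches}
        if len(sizes) > 1:
            raise ValueError(f"patches have mixed shapes: {sizes}")
        return np.stack([p.pixels for p in self._patches])

    def labels(self) -> np.ndarray:
        return self.manifest["class"].to_numpy()

    # ------------------------------------------------------------------ I/O

    def write(self, root: str | Path, *, force: bool = False) -> Path:
        """Write ``root/<domain>/<class>/<patch_id>.png`` + ``manifest.csv``.

        Refuses to overwrite an existing dataset directory unless ``force``.
        """
        root = Path(root)
        if (root / "manifest.csv").exists() and not force:
            raise FileExistsError(f"dataset already exists at {root}; pass force=True to overwrite")
        root.mkdir(parents=True, exist_ok=True)
        for patch in self._patches:
            sub = root / str(patch.domain) / str(patch.label)
            sub.mkdir(parents=True, exist_ok=True)
            Image.fromarray(patch.pixels).save(sub / f"{patch.patch_id}.png")
        self.manifest.to_csv(root / "manifest.csv", index=False)
        return root

    @classmethod
    def read(cls, root: str | Path) -> "PatchDataset":
        root = Path(root)
        manifest = pd.read_csv(root / "manifest.csv", dtype={"patch_id": str})
        patches = []
        for row in manifest.to_dict("records"):  # "class" is a keyword, so no itertuples
            path = root / str(row["domain"]) / str(row["class"]) / f"{row['patch_id']}.png"
            pixels = np.asarray(Image.open(path).convert("RGB"))
            patches.append(
                RgbPatch(
                    pixels,
                    patch_id=str(row["patch_id"]),
                    label=str(row["class"]),
                    domain=str(row["domain"]),
                    x=int(row["x"]),
                    y=int(row["y"]),
                    seed=int(row["seed"]),
                )
            )
        return cls(patches, manifest)

    @classmethod
    def concat(cls, datasets: Sequence["PatchDataset"]) -> "PatchDataset":
        patches: list[RgbPatch] = []
        for ds in datasets:
            patches.extend(list(ds))
        manifest = pd.concat([ds.manifest for ds in datasets], ignore_index=True)
        return cls(patches, manifest)
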