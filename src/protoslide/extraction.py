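"""Annotation-driven patch extraction from slide images.

A slide is tiled on a regular grid (half-open tiles, 0-based pixel
coordinates, x right / y down).  A tile becomes a labeled patch when (a)
at least ``overlap_min`` of its area is covered by annotations of its
majority class (strict-at-the-boundary: exactly 85% is kept) and (b) at
most ``background_max`` of its pixels look like glass background (low
saturation, high value).  Coverage uses pixel-center rasterization: a
pixel belongs to a polygon iff its center lies inside.

Annotations follow the GeoJSON convention of the synthetic slide
generator: a FeatureCollection of Polygons with property
``classification.name``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

from .color import rgb_to_hsv
from .patches import PatchDataset, RgbPatch

__all__ = [
    "AnnotationRegion",
    "PatchCandidate",
    "tile_grid",
    "annotation_overlap_fraction",
    "background_fraction",
    "extract_labeled_patches",
    "regions_from_geojson",
]


@dataclass(frozen=True)
class AnnotationRegion:
    """A labeled polygon in slide pixel coordinates (implicitly closed ring)."""

    polygon: tuple[tuple[float, float], ...]
    label: str

    def __post_init__(self) -> None:
        ring = [tuple(map(float, v)) for v in self.polygon]
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]  # drop explicit closure
        if len(ring) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = shapely.Polygon(ring)
        if not poly.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon for {self.label!r}")
        if poly.area <= 0:
            raise ValueError("polygon must have positive area")
        object.__setattr__(self, "polygon", tuple(ring))

    @property
    def shape(self) -> shapely.Polygon:
        return shapely.Polygon(self.polygon)


def regions_from_geojson(collection: dict) -> list[AnnotationRegion]:
    """Parse a FeatureCollection with ``classification.name`` properties."""
    regions = []
    for feature in collection.get("features", []):
        geom = feature.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        ring = geom["coordinates"][0]
        label = feature.get("properties", {}).get("classification", {}).get("name")
        if label is None:
            raise ValueError("feature lacks classification.name")
        regions.append(AnnotationRegion(polygon=tuple(map(tuple, ring)), label=str(label)))
    return regions


@dataclass
class PatchCandidate:
    """A grid tile with its measured overlap/background fractions."""

    x: int
    y: int
    size: int
    overlap_fraction: float = 0.0
    background_fraction: float = 0.0
    label: str | None = None


def tile_grid(slide_w: int, slide_h: int, size: int, stride: int) -> list[PatchCandidate]:
    """Half-open tiles [x, x+size) x [y, y+size); edge-overhanging tiles dropped.

    Tile count is ``floor((w - size) / stride + 1) * floor((h - size) / stride + 1)``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if size > slide_w or size > slide_h:
        raise ValueError(f"tile size {size} exceeds slide dimensions {slide_w}x{slide_h}")
    xs = range(0, slide_w - size + 1, stride)
    ys = range(0, slide_h - size + 1, stride)
    return [PatchCandidate(x=x, y=y, size=size) for y in ys for x in xs]


def _class_masks(
    regions: Sequence[AnnotationRegion], width: int, height: int
) -> dict[str, np.ndarray]:
    """Pixel-center rasterization of each class's region union."""
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    masks: dict[str, np.ndarray] = {}
    for region in regions:
        inside = shapely.contains_xy(region.shape, gx.ravel(), gy.ravel()).reshape(height, width)
        if region.label in masks:
            masks[region.label] |= inside
        else:
            masks[region.label] = inside
    return masks


def annotation_overlap_fraction(
    candidate: PatchCandidate, regions: Sequence[AnnotationRegion]
) -> tuple[float, str | None]:
    """(covered fraction of the majority class, majority label).

    The fraction counts only pixels covered by regions of the majority
    class — the class with the largest covered area inside the tile; ties
    break lexicographically.  Returns ``(0.0, None)`` when nothing overlaps.
    """
    if not regions:
        return 0.0, None
    x0, y0, size = candidate.x, candidate.y, candidate.size
    xs = np.arange(x0, x0 + size) + 0.5
    ys = np.arange(y0, y0 + size) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    # union per class so overlapping same-class regions are not double-counted
    by_class: dict[str, np.ndarray] = {}
    for region in regions:
        inside = shapely.contains_xy(region.shape, gx.ravel(), gy.ravel())
        if region.label in by_class:
            by_class[region.label] |= inside
        else:
            by_class[region.label] = inside
    areas = {label: int(mask.sum()) for label, mask in by_class.items()}
    best = max(areas.values())
    if best == 0:
        return 0.0, None
    label = min(l for l, a in areas.items() if a == best)
    return best / float(size * size), label


def background_fraction(
    pixels: np.ndarray,
    *,
    saturation_max: float = 0.08,
    value_min: float = 0.85,
) -> float:
    """Fraction of pixels that look like glass: S < 0.08 and V > 0.85."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) patch")
    hsv = rgb_to_hsv(pixels.astype(np.float64) / 255.0)
    bg = (hsv[..., 1] < saturation_max) & (hsv[..., 2] > value_min)
    return float(bg.mean())


def extract_labeled_patches(
    slide: np.ndarray,
    regions: Sequence[AnnotationRegion],
    size: int = 224,
    stride: int | None = None,
    overlap_min: float = 0.85,
    background_max: float = 0.5,
    *,
    domain: str = "slide",
) -> PatchDataset:
    """Tile the slide and keep candidates passing both inclusion rules.

    A tile is kept iff ``overlap_fraction >= overlap_min`` (strict at the
    boundary: 0.85 kept, anything below dropped) and
    ``background_fraction <= background_max``.  The returned manifest's
    (x, y) re-extract bit-identical patches from the source slide.
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3 or slide.dtype != np.uint8:
        raise ValueError("slide must be (H, W, 3) uint8")
    if stride is None:
        stride = size  # non-overlapping grid by default
    height, width = slide.shape[:2]
    candidates = tile_grid(width, height, size, stride)
    if not regions:
        return PatchDataset([])

    # rasterize once per class, then answer per-tile coverage from
    # summed-area tables — equivalent to per-tile pixel-center tests
    masks = _class_masks(regions, width, height)
    labels = sorted(masks)
    integrals = {
        label: np.pad(np.cumsum(np.cumsum(masks[label], axis=0), axis=1), ((1, 0), (1, 0)))
        for label in labels
    }

    def covered(label: str, x: int, y: int) -> int:
        ii = integrals[label]
        return int(ii[y + size, x + size] - ii[y, x + size] - ii[y + size, x] + ii[y, x])

    accepted = []
    for cand in candidates:
        areas = {label: covered(label, cand.x, cand.y) for label in labels}
        best = max(areas.values())
        if best == 0:
            continue
        label = min(l for l, a in areas.items() if a == best)
        cand.overlap_fraction = best / float(size * size)
        if cand.overlap_fraction < overlap_min:
            continue
        tile = slide[cand.y : cand.y + size, cand.x : cand.x + size]
        cand.background_fraction = background_fraction(tile)
        if cand.background_fraction > background_max:
            continue
        cand.label = label
        accepted.append(
            RgbPatch(
                tile.copy(),
                patch_id=f"{domain}-x{cand.x}-y{cand.y}",
                label=label,
                domain=domain,
                x=cand.x,
                y=cand.y,
            )
        )
    return PatchDataset(accepted)
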