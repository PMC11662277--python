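"""Grid tiling, overlap/background rules, and the extraction pipeline
against a per-pixel rasterization oracle."""

import numpy as np
import pytest

from protoslide.extraction import (
    AnnotationRegion,
    PatchCandidate,
    annotation_overlap_fraction,
    background_fraction,
    extract_labeled_patches,
    regions_from_geojson,
    tile_grid,
)
from protoslide.synthetic import (
    default_tissue_classes,
    generate_slide_with_annotations,
)


def point_in_polygon(px, py, ring):
    """Independent even-odd ray-casting oracle."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def oracle_overlap(candidate, regions):
    """Per-pixel scan: fraction of the majority class, majority label."""
    counts = {}
    for region in regions:
        counts.setdefault(region.label, np.zeros((candidate.size, candidate.size), bool))
    for region in regions:
        for dy in range(candidate.size):
            for dx in range(candidate.size):
                if point_in_polygon(
                    candidate.x + dx + 0.5, candidate.y + dy + 0.5, region.polygon
                ):
                    counts[region.label][dy, dx] = True
    areas = {label: int(m.sum()) for label, m in counts.items()}
    best = max(areas.values()) if areas else 0
    if best == 0:
        return 0.0, None
    label = min(l for l, a in areas.items() if a == best)
    return best / candidate.size**2, label


class TestTileGrid:
    @pytest.mark.parametrize(
        "w,h,size,stride,expected",
        [
            (448, 448, 224, 224, 4),
            (224, 224, 224, 224, 1),
            (500, 300, 224, 112, 3),  # floor((500-224)/112+1)=3, floor((300-224)/112+1)=1
            (100, 100, 30, 10, 64),
        ],
    )
    def test_tile_counts_follow_floor_formula(self, w, h, size, stride, expected):
        tiles = tile_grid(w, h, size, stride)
        assert len(tiles) == expected
        assert all(t.x + size <= w and t.y + size <= h for t in tiles)

    def test_single_tile_at_origin(self):
        (tile,) = tile_grid(224, 224, 224, 224)
        assert (tile.x, tile.y) == (0, 0)

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            tile_grid(100, 100, 224, 224)


class TestAnnotationRegion:
    def test_degenerate_polygons_rejected(self):
        with pytest.raises(ValueError):
            AnnotationRegion(((0, 0), (1, 1)), "a")
        with pytest.raises(ValueError):  # bow-tie self-intersection
            AnnotationRegion(((0, 0), (2, 2), (2, 0), (0, 2)), "a")

    def test_explicitly_closed_ring_accepted(self):
        region = AnnotationRegion(((0, 0), (4, 0), (4, 4), (0, 4), (0, 0)), "a")
        assert len(region.polygon) == 4

    def test_geojson_round_trip(self):
        collection = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [8, 0], [8, 8], [0, 8], [0, 0]]],
                    },
                    "properties": {"classification": {"name": "tumor"}},
                }
            ],
        }
        (region,) = regions_from_geojson(collection)
        assert region.label == "tumor"


class TestOverlapFraction:
    def test_patch_strictly_inside_polygon_is_fully_covered(self):
        region = AnnotationRegion(((0, 0), (100, 0), (100, 100), (0, 100)), "tumor")
        frac, label = annotation_overlap_fraction(PatchCandidate(10, 10, 20), [region])
        assert frac == 1.0
        assert label == "tumor"

    def test_half_covered_by_pixel_aligned_rectangle(self):
        region = AnnotationRegion(((0, 0), (10, 0), (10, 20), (0, 20)), "a")
        frac, label = annotation_overlap_fraction(PatchCandidate(0, 0, 20), [region])
        assert frac == 0.5

    def test_no_overlap_returns_zero_and_none(self):
        region = AnnotationRegion(((100, 100), (110, 100), (110, 110), (100, 110)), "a")
        frac, label = annotation_overlap_fraction(PatchCandidate(0, 0, 20), [region])
        assert (frac, label) == (0.0, None)

    def test_majority_tie_breaks_lexicographically(self):
        left = AnnotationRegion(((0, 0), (10, 0), (10, 20), (0, 20)), "b")
        right = AnnotationRegion(((10, 0), (20, 0), (20, 20), (10, 20)), "a")
        _, label = annotation_overlap_fraction(PatchCandidate(0, 0, 20), [left, right])
        assert label == "a"

    def test_matches_per_pixel_oracle_on_random_rectangles(self, rng):
        for _ in range(10):
            x0, y0 = rng.uniform(0, 10, 2)
            w, h = rng.uniform(3, 15, 2)
            region = AnnotationRegion(
                ((x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)), "a"
            )
            cand = PatchCandidate(int(rng.integers(0, 6)), int(rng.integers(0, 6)), 12)
            got = annotation_overlap_fraction(cand, [region])
            want = oracle_overlap(cand, [region])
            assert got == want


class TestBackgroundFraction:
    def test_pure_white_is_all_background(self):
        assert background_fraction(np.full((10, 10, 3), 255, dtype=np.uint8)) == 1.0

    def test_synthetic_tissue_is_mostly_foreground(self, tissue_patch):
        assert background_fraction(tissue_patch) < 0.1

    def test_half_white_half_tissue_composite(self, tissue_patch):
        composite = np.full_like(tissue_patch, 255)
        composite[: tissue_patch.shape[0] // 2] = tissue_patch[: tissue_patch.shape[0] // 2]
        assert background_fraction(composite) == pytest.approx(0.5, abs=0.02)


class TestExtractLabeledPatches:
    def test_strict_85_percent_boundary(self):
        # tile 20x20; rectangle of height 17 covers exactly 340/400 = 0.85
        # (kept); with a 4-pixel notch it covers 336/400 = 0.84 (dropped)
        slide = np.zeros((20, 20, 3), dtype=np.uint8)  # dark = not background
        kept_region = AnnotationRegion(((0, 0), (20, 0), (20, 17), (0, 17)), "a")
        out = extract_labeled_patches(slide, [kept_region], size=20, overlap_min=0.85)
        assert len(out) == 1
        notched = AnnotationRegion(
            ((0, 0), (20, 0), (20, 17), (4, 17), (4, 16), (0, 16)), "a"
        )
        frac, _ = annotation_overlap_fraction(PatchCandidate(0, 0, 20), [notched])
        assert frac == pytest.approx(0.84)
        out = extract_labeled_patches(slide, [notched], size=20, overlap_min=0.85)
        assert len(out) == 0

    def test_no_annotations_yields_empty_dataset(self):
        slide = np.zeros((64, 64, 3), dtype=np.uint8)
        assert len(extract_labeled_patches(slide, [], size=32)) == 0

    def test_background_rule_drops_glass_tiles(self):
        slide = np.full((20, 20, 3), 255, dtype=np.uint8)  # pure glass
        region = AnnotationRegion(((0, 0), (20, 0), (20, 20), (0, 20)), "a")
        assert len(extract_labeled_patches(slide, [region], size=20)) == 0
        assert len(
            extract_labeled_patches(slide, [region], size=20, background_max=1.0)
        ) == 1

    def test_raising_overlap_min_never_admits_more_patches(self):
        slide, geo = generate_slide_with_annotations(3, default_tissue_classes()[:3], 512)
        regions = regions_from_geojson(geo)
        previous = None
        for overlap_min in (0.5, 0.7, 0.85, 0.95):
            n = len(
                extract_labeled_patches(slide, regions, size=48, stride=48,
                                        overlap_min=overlap_min)
            )
            if previous is not None:
                assert n <= previous
            previous = n

    def test_manifest_coordinates_reextract_identical_patches(self):
        slide, geo = generate_slide_with_annotations(4, default_tissue_classes()[:2], 512)
        regions = regions_from_geojson(geo)
        ds = extract_labeled_patches(slide, regions, size=48, stride=48)
        assert len(ds) > 0
        for patch in ds:
            tile = slide[patch.y : patch.y + 48, patch.x : patch.x + 48]
            assert np.array_equal(tile, patch.pixels)

    def test_accepted_set_matches_per_tile_oracle(self):
        slide, geo = generate_slide_with_annotations(11, default_tissue_classes()[:3], 512)
        regions = regions_from_geojson(geo)
        ds = extract_labeled_patches(slide, regions, size=64, stride=64)
        accepted = {(p.x, p.y): p.label for p in ds}
        oracle = {}
        for tile in tile_grid(512, 512, 64, 64):
            frac, label = annotation_overlap_fraction(tile, regions)
            if frac >= 0.85 and label is not None:
                pixels = slide[tile.y : tile.y + 64, tile.x : tile.x + 64]
                if background_fraction(pixels) <= 0.5:
                    oracle[(tile.x, tile.y)] = label
        assert accepted == oracle
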