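"""Seeded generator of H&E-like patches, multi-domain datasets, and slides.

Real histopathology data cannot ship with the package, so every component
is exercised on procedural stand-ins: tissue classes are rendered as
random-ellipse "nuclei" in the hematoxylin optical-density channel over a
smooth "stromal" eosin texture, composed through the same stain matrix the
augmentation module inverts (so color deconvolution is exercised in both
directions).  Scanner domains are forward models of digitization
variability — hue rotation, saturation scaling, per-channel gain/offset,
defocus blur, and sensor noise — applied in that fixed order.

Everything is a pure function of its spec and seed: the same inputs yield
bit-identical images.  Child seeds are derived from the master seed with a
splitmix64 mixing function, so generation order never matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .augment import hue_jitter, saturation_jitter
from .patches import PatchDataset, RgbPatch
from .stains import RUIFROK_JOHNSTON_HE, StainMatrix, hed_to_rgb

__all__ = [
    "TissueClassSpec",
    "ScannerProfile",
    "SyntheticDatasetSpec",
    "IDENTITY_SCANNER",
    "generate_patch",
    "apply_scanner",
    "generate_dataset",
    "generate_slide_with_annotations",
    "default_tissue_classes",
    "default_scanner_profiles",
    "mix_seed",
]

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    """One step of the splitmix64 mixing function (public-domain constants)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def mix_seed(*parts: int) -> int:
    """Mix integers into one 63-bit child seed (order-sensitive)."""
    state = 0
    for part in parts:
        state = _splitmix64(state ^ (int(part) & _MASK64))
    return state >> 1  # keep it non-negative / below 2**63


@dataclass(frozen=True)
class TissueClassSpec:
    """Generative parameters of one synthetic tissue class.

    ``nucleus_density`` is the expected nucleus count per 10^4 px^2;
    ``hematoxylin_level`` / ``eosin_level`` are mean optical densities of
    nuclei (H channel) and background (E channel).
    """

    name: str
    nucleus_density: float
    nucleus_radius_mean: float
    nucleus_radius_sd: float
    hematoxylin_level: float
    eosin_level: float
    texture_seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd <= 0:
            raise ValueError("nucleus radii must be > 0")
        if self.hematoxylin_level < 0 or self.eosin_level < 0:
            raise ValueError("optical densities must be >= 0")

    def generative_params(self) -> tuple:
        return (
            self.nucleus_density,
            self.nucleus_radius_mean,
            self.nucleus_radius_sd,
            self.hematoxylin_level,
            self.eosin_level,
            self.texture_seed_offset,
        )


@dataclass(frozen=True)
class ScannerProfile:
    """Forward model of one digitization domain.

    The transform order is fixed: hue rotation -> saturation scaling ->
    per-channel gain/offset -> Gaussian blur -> additive Gaussian noise.
    The identity profile maps any image to itself bit-exactly (each step
    is skipped when its parameter is the identity).
    """

    name: str
    hue_shift_deg: float = 0.0
    saturation_scale: float = 1.0
    channel_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blur_sigma: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.saturation_scale <= 0:
            raise ValueError("saturation_scale must be > 0")
        if len(self.channel_gain) != 3 or any(g <= 0 for g in self.channel_gain):
            raise ValueError("channel_gain must be three positive factors")
        if len(self.channel_offset) != 3 or any(abs(o) > 0.2 for o in self.channel_offset):
            raise ValueError("channel_offset components must lie in [-0.2, 0.2]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.hue_shift_deg == 0
            and self.saturation_scale == 1.0
            and tuple(self.channel_gain) == (1.0, 1.0, 1.0)
            and tuple(self.channel_offset) == (0.0, 0.0, 0.0)
            and self.blur_sigma == 0.0
            and self.noise_sd == 0.0
        )


IDENTITY_SCANNER = ScannerProfile(name="identity")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    classes: tuple[TissueClassSpec, ...]
    scanners: tuple[ScannerProfile, ...]
    patches_per_class_per_scanner: int
    patch_size: int = 64
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.patches_per_class_per_scanner <= 0:
            raise ValueError("patches_per_class_per_scanner must be > 0")
        if self.patch_size < 16:
            raise ValueError("patch_size must be >= 16")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        scanner_names = [s.name for s in self.scanners]
        if len(set(scanner_names)) != len(scanner_names):
            raise ValueError("scanner names must be unique")
        # separability precondition: differently named classes must differ
        # in at least one generative parameter
        params = {}
        for c in self.classes:
            key = c.generative_params()
            if key in params:
                raise ValueError(
                    f"classes {params[key]!r} and {c.name!r} share identical generative parameters"
                )
            params[key] = c.name


# --------------------------------------------------------------- rendering


def _render_tissue_od(
    cls: TissueClassSpec, height: int, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Render an (H, W, 3) hematoxylin/eosin/residual optical-density field."""
    # smooth eosin texture: low-pass filtered white noise, min-max normalized
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, min(height, width) / 16.0))
    span = smooth.max() - smooth.min()
    texture = (smooth - smooth.min()) / span if span > 0 else np.zeros_like(smooth)
    eosin = cls.eosin_level * (0.55 + 0.45 * texture)

    hema = np.full((height, width), 0.03)
    nucleus_mask = np.zeros((height, width))

    n_nuclei = rng.poisson(cls.nucleus_density * height * width / 1e4)
    ys, xs = np.mgrid[0:height, 0:width]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, height), rng.uniform(0, width)
        a = max(1.0, rng.normal(cls.nucleus_radius_mean, cls.nucleus_radius_sd))
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        level = cls.hematoxylin_level * rng.uniform(0.75, 1.25)
        # bounding box clip keeps per-nucleus work O(radius^2)
        r = int(np.ceil(max(a, b))) + 2
        y0, y1 = max(0, int(cy) - r), min(height, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(width, int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = ys[y0:y1, x0:x1] - cy
        dx = xs[y0:y1, x0:x1] - cx
        xr = dx * np.cos(theta) + dy * np.sin(theta)
        yr = -dx * np.sin(theta) + dy * np.cos(theta)
        r2 = (xr / a) ** 2 + (yr / b) ** 2
        m = np.clip((1.15 - r2) / 0.3, 0.0, 1.0)  # soft-edged ellipse
        hema[y0:y1, x0:x1] += level * m
        nucleus_mask[y0:y1, x0:x1] = np.maximum(nucleus_mask[y0:y1, x0:x1], m)

    eosin = eosin * (1.0 - 0.35 * nucleus_mask)  # nuclei displace cytoplasm
    residual = np.zeros_like(hema)
    return np.stack([hema, eosin, residual], axis=-1)


def apply_scanner(
    pixels: np.ndarray,
    profile: ScannerProfile,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply a scanner's forward transform to an 8-bit RGB image.

    Steps run in the fixed order hue -> saturation -> gain/offset -> blur
    -> noise; identity parameters skip their step so the identity profile
    is bit-exact.  ``rng`` is only required when ``noise_sd > 0``.
    """
    out = np.asarray(pixels)
    if out.dtype != np.uint8:
        raise ValueError("apply_scanner expects uint8 pixels")
    if profile.hue_shift_deg != 0:
        out = hue_jitter(out, shift_deg=profile.hue_shift_deg)
    if profile.saturation_scale != 1.0:
        out = saturation_jitter(out, scale=profile.saturation_scale)
    gain = np.asarray(profile.channel_gain, dtype=np.float64)
    offset = np.asarray(profile.channel_offset, dtype=np.float64)
    if np.any(gain != 1.0) or np.any(offset != 0.0):
        x = out.astype(np.float64) / 255.0 * gain + offset
        out = np.rint(np.clip(x, 0.0, 1.0) * 255.0).astype(np.uint8)
    if profile.blur_sigma > 0:
        x = ndimage.gaussian_filter(
            out.astype(np.float32), sigma=(profile.blur_sigma, profile.blur_sigma, 0.0),
            mode="reflect",
        )
        out = np.rint(np.clip(x, 0.0, 255.0)).astype(np.uint8)
    if profile.noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required for noise_sd > 0")
        x = out.astype(np.float64) / 255.0 + rng.normal(0.0, profile.noise_sd, out.shape)
        out = np.rint(np.clip(x, 0.0, 1.0) * 255.0).astype(np.uint8)
    return out


def generate_patch(
    cls: TissueClassSpec,
    scanner: ScannerProfile,
    size: int,
    seed: int,
    *,
    matrix: StainMatrix = RUIFROK_JOHNSTON_HE,
) -> RgbPatch:
    """Render one synthetic H&E patch under a scanner domain.

    Deterministic in ``(cls, scanner, size, seed)``; the texture stream is
    offset by ``cls.texture_seed_offset`` so classes sharing a seed do not
    share nucleus layouts.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & _MASK64 >> 1, cls.texture_seed_offset & 0xFFFF])
    )
    od = _render_tissue_od(cls, size, size, rng)
    base = hed_to_rgb(od, matrix)
    pixels = apply_scanner(base, scanner, rng)
    return RgbPatch(
        pixels,
        patch_id=f"{scanner.name}-{cls.name}-{seed & 0xFFFFFFFF:08x}",
        label=cls.name,
        domain=scanner.name,
        seed=int(seed),
    )


# ---------------------------------------------------------------- datasets


def generate_dataset(
    spec: SyntheticDatasetSpec,
    out_dir: str | Path | None = None,
    *,
    force: bool = False,
) -> PatchDataset:
    """Generate the full multi-domain dataset described by ``spec``.

    Child seed for patch ``p`` of class ``c`` under scanner ``d`` is
    ``mix_seed(master_seed, d, c, p)``.  When ``out_dir`` is given the
    dataset is also written in the standard layout (refusing to overwrite
    an existing dataset unless ``force``).
    """
    patches = []
    for d_idx, scanner in enumerate(spec.scanners):
        for c_idx, cls in enumerate(spec.classes):
            for p_idx in range(spec.patches_per_class_per_scanner):
                child = mix_seed(spec.master_seed, d_idx, c_idx, p_idx)
                patch = generate_patch(cls, scanner, spec.patch_size, child)
                patch.patch_id = f"{scanner.name}-{cls.name}-{p_idx:04d}"
                patches.append(patch)
    dataset = PatchDataset(patches)
    if out_dir is not None:
        dataset.write(out_dir, force=force)
    return dataset


# ------------------------------------------------------------------ slides


def _octagon(x0: float, y0: float, w: float, h: float, cut: float) -> list[list[float]]:
    """Axis-aligned rectangle with cut corners, as a closed coordinate ring."""
    cx = cut * min(w, h)
    return [
        [x0 + cx, y0],
        [x0 + w - cx, y0],
        [x0 + w, y0 + cx],
        [x0 + w, y0 + h - cx],
        [x0 + w - cx, y0 + h],
        [x0 + cx, y0 + h],
        [x0, y0 + h - cx],
        [x0, y0 + cx],
        [x0 + cx, y0],
    ]


def generate_slide_with_annotations(
    layout_seed: int,
    classes: Sequence[TissueClassSpec],
    size: int,
    *,
    scanner: ScannerProfile = IDENTITY_SCANNER,
    max_tries: int = 200,
) -> tuple[np.ndarray, dict]:
    """Compose a slide-scale image of non-overlapping class regions.

    Returns the slide as an ``(size, size, 3)`` uint8 array on a white
    background and a GeoJSON FeatureCollection with one polygon feature
    per region (property ``classification.name``; slide pixel coordinate
    frame, 0-based, x right / y down).
    """
    import shapely

    if size < 512:
        raise ValueError("slide size must be >= 512")
    rng = np.random.default_rng(np.random.SeedSequence([int(layout_seed) & (_MASK64 >> 1)]))
    slide = np.full((size, size, 3), 255, dtype=np.uint8)
    features = []
    placed: list[tuple[float, float, float, float]] = []
    for cls in classes:
        for attempt in range(max_tries + 1):
            if attempt == max_tries:
                raise RuntimeError(
                    f"could not place region for class {cls.name!r} without overlap"
                )
            w = rng.uniform(size / 6, size / 3)
            h = rng.uniform(size / 6, size / 3)
            x0 = rng.uniform(0, size - w)
            y0 = rng.uniform(0, size - h)
            if all(
                x0 + w <= px or px + pw <= x0 or y0 + h <= py or ph + py <= y0
                for (px, py, pw, ph) in placed
            ):
                placed.append((x0, y0, w, h))
                break
        ring = _octagon(x0, y0, w, h, cut=0.2)
        poly = shapely.Polygon(ring)
        # rasterize by pixel centers and paint class texture inside
        xmin, ymin = int(np.floor(x0)), int(np.floor(y0))
        xmax, ymax = int(np.ceil(x0 + w)), int(np.ceil(y0 + h))
        xs = np.arange(xmin, xmax) + 0.5
        ys = np.arange(ymin, ymax) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        mask = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        tex_rng = np.random.default_rng(
            np.random.SeedSequence([int(layout_seed) & (_MASK64 >> 1), len(features) + 1])
        )
        od = _render_tissue_od(cls, ymax - ymin, xmax - xmin, tex_rng)
        tex = hed_to_rgb(od)
        tex = apply_scanner(tex, scanner, tex_rng)
        region = slide[ymin:ymax, xmin:xmax]
        region[mask] = tex[mask]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": {"name": cls.name}},
            }
        )
    return slide, {"type": "FeatureCollection", "features": features}


def save_annotations(annotations: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotations, indent=2))


def load_annotations(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------- default specs


def default_tissue_classes() -> tuple[TissueClassSpec, ...]:
    """Four texture- and stain-distinct classes used by the benchmark.

    Classes are separated along two axes that survive scanner shifts
    differently: the hematoxylin:eosin mix ratio (which sets the hue of a
    patch and is invariant to a global saturation change) and nucleus
    texture (density and size).  Relying on stain *amount* alone would
    make neighboring classes collide under a saturation shift, so the
    ratios are kept well apart: inflammation is strongly
    hematoxylin-dominated with dense tiny nuclei, tumor
    hematoxylin-leaning with large crowded nuclei, mucosa balanced with
    glandular medium nuclei, and stroma eosin-dominated with sparse small
    nuclei.
    """
    return (
        TissueClassSpec("inflammation", 80.0, 1.6, 0.30, 0.95, 0.15, texture_seed_offset=3),
        TissueClassSpec("mucosa", 22.0, 3.4, 0.60, 0.45, 0.55, texture_seed_offset=2),
        TissueClassSpec("stroma", 5.0, 2.2, 0.45, 0.20, 0.80, texture_seed_offset=1),
        TissueClassSpec("tumor", 40.0, 4.5, 0.80, 0.85, 0.45, texture_seed_offset=0),
    )


def default_scanner_profiles() -> tuple[ScannerProfile, ...]:
    """One identity base domain plus three shifted 'scanners'.

    Shift magnitudes mirror the kind of variation seen between real slide
    scanners (hue/saturation drift, white-balance gain, slight defocus,
    sensor noise) and stay within the coverage of the default augmentation
    policy (hue +-20 deg, saturation +-25%, blur <= 2 px).
    """
    return (
        ScannerProfile("scanner_a"),
        ScannerProfile(
            "scanner_b",
            hue_shift_deg=15.0,
            saturation_scale=1.20,
            channel_gain=(1.04, 0.98, 1.00),
            noise_sd=0.01,
        ),
        ScannerProfile(
            "scanner_c",
            hue_shift_deg=-12.0,
            saturation_scale=0.72,
            channel_gain=(0.97, 1.00, 1.05),
            channel_offset=(0.02, 0.02, 0.02),
            blur_sigma=0.6,
            noise_sd=0.008,
        ),
        ScannerProfile(
            "scanner_d",
            hue_shift_deg=8.0,
            saturation_scale=0.90,
            channel_offset=(-0.03, -0.01, 0.02),
            blur_sigma=1.4,
            noise_sd=0.02,
        ),
    )
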