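"""Training-time augmentations emulating stain and scanner variability.

Four augmentations are provided, mirroring the variance seen between slide
scanners and staining sites:

* :func:`hed_jitter` — the stain-specific scheme of Tellez et al.: the
  image is color-deconvolved into hematoxylin/eosin/residual optical
  densities, each stain channel is scaled and shifted independently
  (``OD' = alpha * OD + beta``), and the image is recomposed.
* :func:`hue_jitter` — a single random rotation of the HSV hue circle;
  saturation and value are untouched.
* :func:`saturation_jitter` — a single multiplicative saturation scale;
  hue and value are untouched.
* :func:`gaussian_blur` — per-channel Gaussian smoothing simulating
  out-of-focus regions introduced during scanning.

All functions accept a single ``(H, W, 3)`` patch or a ``(B, H, W, 3)``
batch of 8-bit sRGB pixels and return uint8 of the same shape; random
parameters are drawn per image from the supplied generator, so results are
reproducible given an rng state.  :class:`AugmentationPolicy` composes the
four into the stochastic policy applied during episodic training (color
augmentations fire with probability 0.5 each, blur with 0.3, by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .color import hsv_to_rgb, rgb_to_hsv
from .patches import RgbPatch, as_pixel_array
from .stains import RUIFROK_JOHNSTON_HE, StainMatrix

__all__ = [
    "hed_jitter",
    "hue_jitter",
    "saturation_jitter",
    "gaussian_blur",
    "AugmentationPolicy",
    "apply_policy",
    "augment_batch",
]


def _as_batch(pixels: np.ndarray) -> tuple[np.ndarray, bool]:
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        return pixels[None], True
    if pixels.ndim == 4:
        return pixels, False
    raise ValueError(f"expected (H, W, 3) or (B, H, W, 3), got {pixels.shape}")


def _unbatch(batch: np.ndarray, squeeze: bool) -> np.ndarray:
    return batch[0] if squeeze else batch


def _per_image(value: float | np.ndarray, n: int, trailing: tuple[int, ...]) -> np.ndarray:
    """Broadcast a forced parameter to one value per image."""
    arr = np.asarray(value, dtype=np.float64)
    target = (n,) + trailing
    return np.broadcast_to(arr, target) if arr.shape != target else arr


def hed_jitter(
    pixels: np.ndarray | RgbPatch,
    alpha_sigma: float = 0.05,
    beta_sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    *,
    alpha: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    matrix: StainMatrix = RUIFROK_JOHNSTON_HE,
) -> np.ndarray:
    """Scale/shift each stain's optical density independently.

    Per stain channel i: ``OD'_i = alpha_i * OD_i + beta_i`` with
    ``alpha_i ~ U(1 - alpha_sigma, 1 + alpha_sigma)`` and
    ``beta_i ~ U(-beta_sigma, beta_sigma)``, then reconversion to RGB.
    ``alpha``/``beta`` override the random draw (shape ``(3,)`` or ``(B, 3)``).
    """
    if alpha_sigma < 0 or beta_sigma < 0:
        raise ValueError("jitter magnitudes must be non-negative")
    batch, squeeze = _as_batch(as_pixel_array(pixels) if isinstance(pixels, RgbPatch) else pixels)
    n = batch.shape[0]
    if alpha is None:
        rng = _require_rng(rng)
        alpha = rng.uniform(1.0 - alpha_sigma, 1.0 + alpha_sigma, size=(n, 3))
    if beta is None:
        rng = _require_rng(rng)
        beta = rng.uniform(-beta_sigma, beta_sigma, size=(n, 3))
    alpha = _per_image(alpha, n, (3,))[:, None, None, :].astype(np.float32)
    beta = _per_image(beta, n, (3,))[:, None, None, :].astype(np.float32)
    # float32 pipeline: the deconvolve-jitter-recompose round trip is hot in
    # the training loop, and float32 error is far below 8-bit quantization
    x = batch.astype(np.float32)
    od = -np.log10((x + np.float32(1e-6)) / np.float32(255.0))
    hed = od @ matrix.inverse.astype(np.float32)
    od_rgb = (hed * alpha + beta) @ matrix.rows.astype(np.float32)
    ln10 = np.float32(np.log(10.0))
    rgb = np.float32(255.0) * np.exp(-od_rgb * ln10) - np.float32(1e-6)
    out = np.rint(np.clip(rgb, 0.0, 255.0)).astype(np.uint8)
    return _unbatch(out, squeeze)


def hue_jitter(
    pixels: np.ndarray | RgbPatch,
    max_shift_deg: float = 20.0,
    rng: np.random.Generator | None = None,
    *,
    shift_deg: float | np.ndarray | None = None,
) -> np.ndarray:
    """Rotate the hue of every pixel by one random angle; S and V unchanged."""
    if not 0.0 <= max_shift_deg <= 180.0:
        raise ValueError("max_shift_deg must lie in [0, 180]")
    batch, squeeze = _as_batch(as_pixel_array(pixels) if isinstance(pixels, RgbPatch) else pixels)
    n = batch.shape[0]
    if shift_deg is None:
        rng = _require_rng(rng)
        shift_deg = rng.uniform(-max_shift_deg, max_shift_deg, size=n)
    shift = _per_image(shift_deg, n, ())[:, None, None] / 360.0
    hsv = rgb_to_hsv(batch.astype(np.float32) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
    out = np.rint(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)
    return _unbatch(out, squeeze)


def saturation_jitter(
    pixels: np.ndarray | RgbPatch,
    sigma: float = 0.25,
    rng: np.random.Generator | None = None,
    *,
    scale: float | np.ndarray | None = None,
) -> np.ndarray:
    """Scale the saturation of every pixel by one random factor; H, V unchanged."""
    if not 0.0 <= sigma < 1.0:
        raise ValueError("sigma must lie in [0, 1)")
    batch, squeeze = _as_batch(as_pixel_array(pixels) if isinstance(pixels, RgbPatch) else pixels)
    n = batch.shape[0]
    if scale is None:
        rng = _require_rng(rng)
        scale = rng.uniform(1.0 - sigma, 1.0 + sigma, size=n)
    s = _per_image(scale, n, ())[:, None, None]
    hsv = rgb_to_hsv(batch.astype(np.float32) / 255.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * s, 0.0, 1.0)
    out = np.rint(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)
    return _unbatch(out, squeeze)


def gaussian_blur(
    pixels: np.ndarray | RgbPatch,
    sigma_max: float = 2.0,
    rng: np.random.Generator | None = None,
    *,
    sigma: float | np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel Gaussian blur with reflect padding, sigma ~ U(0, sigma_max]."""
    if sigma_max <= 0:
        raise ValueError("sigma_max must be positive")
    batch, squeeze = _as_batch(as_pixel_array(pixels) if isinstance(pixels, RgbPatch) else pixels)
    n = batch.shape[0]
    if sigma is None:
        rng = _require_rng(rng)
        sigma = rng.uniform(0.0, sigma_max, size=n)
    sig = _per_image(sigma, n, ())
    out = np.empty_like(batch)
    for i in range(n):
        if sig[i] <= 0:
            out[i] = batch[i]
            continue
        blurred = ndimage.gaussian_filter(
            batch[i].astype(np.float32), sigma=(float(sig[i]), float(sig[i]), 0.0), mode="reflect"
        )
        out[i] = np.rint(np.clip(blurred, 0.0, 255.0)).astype(np.uint8)
    return _unbatch(out, squeeze)


def _require_rng(rng: np.random.Generator | None) -> np.random.Generator:
    if rng is None:
        raise ValueError("an rng is required when parameters are not forced")
    return rng


_AUGMENTATIONS = {
    "hed_jitter": hed_jitter,
    "hue_jitter": hue_jitter,
    "saturation_jitter": saturation_jitter,
    "gaussian_blur": gaussian_blur,
}


@dataclass(frozen=True)
class AugmentationItem:
    name: str
    p: float
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _AUGMENTATIONS:
            raise ValueError(
                f"unknown augmentation {self.name!r}; known: {sorted(_AUGMENTATIONS)}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("application probability must lie in [0, 1]")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ordered list of augmentations, each firing independently with its p."""

    items: tuple[AugmentationItem, ...]

    @classmethod
    def default(cls) -> "AugmentationPolicy":
        return cls(
            items=(
                AugmentationItem("hed_jitter", 0.5, {"alpha_sigma": 0.05, "beta_sigma": 0.05}),
                AugmentationItem("hue_jitter", 0.5, {"max_shift_deg": 20.0}),
                AugmentationItem("saturation_jitter", 0.5, {"sigma": 0.25}),
                AugmentationItem("gaussian_blur", 0.3, {"sigma_max": 2.0}),
            )
        )

    @classmethod
    def from_config(cls, entries: Sequence[Mapping[str, Any]]) -> "AugmentationPolicy":
        """Build from the ``augmentation:`` section of a YAML run config."""
        return cls(
            items=tuple(
                AugmentationItem(e["name"], float(e.get("p", 1.0)), dict(e.get("params", {})))
                for e in entries
            )
        )

    def to_config(self) -> list[dict[str, Any]]:
        return [{"name": i.name, "p": i.p, "params": dict(i.params)} for i in self.items]


def apply_policy(
    patch: np.ndarray | RgbPatch,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Apply a policy to one patch; returns (patch, names of items that fired)."""
    pixels = as_pixel_array(patch)
    fired: list[str] = []
    for item in policy.items:
        if rng.random() < item.p:
            pixels = _AUGMENTATIONS[item.name](pixels, rng=rng, **item.params)
            fired.append(item.name)
    return pixels, fired


def _hsv_hue_sat_batch(
    batch: np.ndarray, shift: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """One combined HSV round trip applying per-image hue shift (+) and
    saturation scale (*); float32, channel planes kept contiguous."""
    x = batch.astype(np.float32) / np.float32(255.0)
    planes = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    r, g, b = planes[:, 0], planes[:, 1], planes[:, 2]
    v = np.maximum(np.maximum(r, g), b)
    c = v - np.minimum(np.minimum(r, g), b)
    safe_c = np.where(c == 0, 1, c)
    h6 = np.where(
        v == r,
        (g - b) / safe_c,
        np.where(v == g, 2.0 + (b - r) / safe_c, 4.0 + (r - g) / safe_c),
    )  # hue * 6, in (-1, 5]
    h6 = np.where(h6 < 0, h6 + 6.0, h6)
    h6 = np.where(c == 0, 0.0, h6)
    s = np.where(v == 0, 0.0, c / np.where(v == 0, 1, v))
    # wrap via floor instead of fmod (fmod dominates the profile otherwise)
    h6 = h6 + 6.0 * shift.astype(np.float32)[:, None, None]
    h6 -= 6.0 * np.floor(h6 / 6.0)
    s = np.clip(s * scale.astype(np.float32)[:, None, None], 0.0, 1.0)
    vs = v * s

    def channel(n: float) -> np.ndarray:
        k = np.float32(n) + h6  # in [n, n + 6)
        k = np.where(k >= 6.0, k - 6.0, k)
        return v - vs * np.clip(np.minimum(k, 4.0 - k), 0.0, 1.0)

    out = np.stack([channel(5.0), channel(3.0), channel(1.0)], axis=-1)
    return np.rint(out * np.float32(255.0)).astype(np.uint8)


def augment_batch(
    batch: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized policy application over a ``(B, H, W, 3)`` uint8 batch.

    Each item fires independently per image; parameters are drawn per
    firing image, with the same draw order as :func:`apply_policy` applied
    image-wise.  Consecutive hue/saturation items are fused into a single
    HSV round trip (both operate in HSV space, so fusing only removes one
    intermediate 8-bit quantization).  Used by the episodic training loop,
    where per-patch python dispatch would dominate the step time.
    """
    batch = np.asarray(batch)
    if batch.ndim != 4:
        raise ValueError(f"expected (B, H, W, 3), got {batch.shape}")
    out = batch.copy()
    n = batch.shape[0]
    i = 0
    while i < len(policy.items):
        item = policy.items[i]
        nxt = policy.items[i + 1] if i + 1 < len(policy.items) else None
        if (
            item.name == "hue_jitter"
            and nxt is not None
            and nxt.name == "saturation_jitter"
        ):
            fires_h = rng.random(n) < item.p
            shift = np.zeros(n)
            if fires_h.any():
                max_shift = float(item.params.get("max_shift_deg", 20.0))
                shift[fires_h] = rng.uniform(-max_shift, max_shift, fires_h.sum()) / 360.0
            fires_s = rng.random(n) < nxt.p
            scale = np.ones(n)
            if fires_s.any():
                sigma = float(nxt.params.get("sigma", 0.25))
                scale[fires_s] = rng.uniform(1.0 - sigma, 1.0 + sigma, fires_s.sum())
            touched = fires_h | fires_s
            if touched.any():
                idx = np.flatnonzero(touched)
                out[idx] = _hsv_hue_sat_batch(out[idx], shift[idx], scale[idx])
            i += 2
            continue
        fires = rng.random(n) < item.p
        if fires.any():
            idx = np.flatnonzero(fires)
            out[idx] = _AUGMENTATIONS[item.name](out[idx], rng=rng, **item.params)
        i += 1
    return out
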