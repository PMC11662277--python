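"""Vectorized RGB <-> HSV conversion on unit-scale float arrays.

The hue channel lives on the unit circle (``H`` in ``[0, 1)``); saturation
and value are in ``[0, 1]``.  The implementation is dtype-preserving so the
training loop can run the hue/saturation augmentations in float32 on whole
episode batches; it matches ``skimage.color.rgb2hsv``/``hsv2rgb`` to within
float rounding (the test suite cross-checks against scikit-image).
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsv", "hsv_to_rgb"]


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Convert ``(..., 3)`` RGB in [0, 1] to HSV with hue in [0, 1)."""
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis, got shape {rgb.shape}")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = np.maximum(np.maximum(r, g), b)
    c = v - np.minimum(np.minimum(r, g), b)
    safe_c = np.where(c == 0, 1, c)
    h = np.where(
        v == r,
        (g - b) / safe_c,
        np.where(v == g, 2.0 + (b - r) / safe_c, 4.0 + (r - g) / safe_c),
    )
    h = (h / 6.0) % 1.0
    h = np.where(c == 0, 0.0, h)
    safe_v = np.where(v == 0, 1, v)
    s = np.where(v == 0, 0.0, c / safe_v)
    return np.stack([h, s, v], axis=-1).astype(rgb.dtype, copy=False)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; hue is taken modulo 1.

    Uses the branch-free formulation ``f(n) = V - V*S*clip(min(k, 4-k), 0, 1)``
    with ``k = (n + 6H) mod 6`` and ``n = 5, 3, 1`` for R, G, B.
    """
    hsv = np.asarray(hsv)
    if hsv.shape[-1] != 3:
        raise ValueError(f"expected trailing HSV axis, got shape {hsv.shape}")
    h6 = (hsv[..., 0] % 1.0) * 6.0
    vs = hsv[..., 2] * hsv[..., 1]
    v = hsv[..., 2]

    def channel(n: float) -> np.ndarray:
        k = (n + h6) % 6.0
        return v - vs * np.clip(np.minimum(k, 4.0 - k), 0.0, 1.0)

    return np.stack([channel(5.0), channel(3.0), channel(1.0)], axis=-1).astype(
        hsv.dtype, copy=False
    )
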