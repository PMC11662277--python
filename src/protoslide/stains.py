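"""RGB <-> stain optical-density conversion for H&E imagery.

Color deconvolution separates the contribution of hematoxylin (nuclei) and
eosin (stroma/cytoplasm) per pixel by log-transforming transmitted light
into optical density (OD) and projecting onto per-stain absorption vectors.
The conventions used throughout the package are fixed here:

* intensities are 8-bit with white level ``I0 = 255``,
* ``OD = -log10((I + eps) / I0)`` with ``eps = 1e-6``,
* the default stain matrix is the Ruifrok–Johnston H&E(+residual) matrix,
  row-normalized to unit Euclidean norm.

The forward map (:func:`hed_to_rgb`) and the deconvolution
(:func:`rgb_to_hed`) are exact mutual inverses up to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "RUIFROK_JOHNSTON_HE",
    "rgb_to_hed",
    "hed_to_rgb",
    "I0",
    "OD_EPS",
]

#: White transmission level of an 8-bit image.
I0 = 255.0

#: Regularizer keeping the optical density finite for zero-intensity pixels.
OD_EPS = 1e-6


class SingularStainMatrixError(ValueError):
    """Raised when the stain vectors do not span RGB OD space."""


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-norm stain absorption vectors in optical-density RGB space.

    Rows are (hematoxylin, eosin, residual).  The matrix maps stain
    densities to RGB optical densities: ``OD_rgb = HED @ rows``.
    """

    rows: np.ndarray = field()

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {rows.shape}")
        norms = np.linalg.norm(rows, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain vectors must have unit Euclidean norm")
        if abs(np.linalg.det(rows)) < 1e-8:
            raise SingularStainMatrixError("stain vectors are linearly dependent")
        rows.setflags(write=False)
        object.__setattr__(self, "rows", rows)

    @classmethod
    def from_unnormalized(cls, rows: np.ndarray) -> "StainMatrix":
        rows = np.asarray(rows, dtype=np.float64)
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise SingularStainMatrixError("zero stain vector")
        return cls(rows / norms)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.rows)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.rows))


# Ruifrok & Johnston H&E absorption vectors plus the residual (cross-product)
# channel; rows are normalized by the constructor.
RUIFROK_JOHNSTON_HE = StainMatrix.from_unnormalized(
    np.array(
        [
            [0.65, 0.70, 0.29],
            [0.07, 0.99, 0.11],
            [0.27, 0.57, 0.78],
        ]
    )
)


def _as_float_rgb(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim < 1 or pixels.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {pixels.shape}")
    return pixels.astype(np.float64, copy=False)


def rgb_to_hed(pixels: np.ndarray, matrix: StainMatrix = RUIFROK_JOHNSTON_HE) -> np.ndarray:
    """Deconvolve 8-bit RGB into (hematoxylin, eosin, residual) densities.

    Parameters
    ----------
    pixels
        ``(..., 3)`` array of 8-bit RGB intensities (any integer or float
        dtype on the 0..255 scale).
    matrix
        Stain matrix whose rows span OD space.

    Returns
    -------
    ``(..., 3)`` float array of per-stain optical densities (finite).
    """
    rgb = _as_float_rgb(pixels)
    od = -np.log10((rgb + OD_EPS) / I0)
    return od @ matrix.inverse


def hed_to_rgb(
    densities: np.ndarray,
    matrix: StainMatrix = RUIFROK_JOHNSTON_HE,
    *,
    quantize: bool = True,
) -> np.ndarray:
    """Recompose stain optical densities into an 8-bit RGB image.

    ``I = I0 * 10**(-(HED @ rows)) - eps``, clipped to [0, 255].  With
    ``quantize=False`` the unclipped-to-integer float image is returned
    (still clipped to the valid range), which the augmentations use to
    avoid double quantization.
    """
    densities = np.asarray(densities, dtype=np.float64)
    if densities.shape[-1] != 3:
        raise ValueError(f"expected trailing stain axis of size 3, got {densities.shape}")
    if not np.all(np.isfinite(densities)):
        raise ValueError("stain densities must be finite")
    od_rgb = densities @ matrix.rows
    rgb = I0 * np.power(10.0, -od_rgb) - OD_EPS
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        return np.rint(rgb).astype(np.uint8)
    return rgb
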