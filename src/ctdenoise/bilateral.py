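"""Edge-preserving bilateral filter.

Each output pixel is the normalized weighted average of its square
neighborhood, the weight being the product of a spatial Gaussian closeness
kernel (width ``sigma_d``, pixels) and a range Gaussian photometric kernel
(width ``sigma_r``, intensity units):

    w(i,j,k,l) = exp(-((i-k)^2 + (j-l)^2) / (2 sigma_d^2))
               * exp(-(f(i,j) - f(k,l))^2 / (2 sigma_r^2))

    g(i,j) = sum f(k,l) w(i,j,k,l) / sum w(i,j,k,l)

Flat regions are smoothed like a plain Gaussian blur while strong edges
survive, because neighbors across an edge receive near-zero range weight.
Boundaries use symmetric reflection so the normalization never sees
artificial zeros. The implementation loops over window offsets (not over
pixels), so it is exact — no grid or lattice approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BilateralParams", "bilateral_filter"]


@dataclass(frozen=True)
class BilateralParams:
    """Spatial/range kernel widths and window radius.

    ``radius=None`` defaults to ``ceil(2 * sigma_d)``, wide enough that the
    truncated spatial Gaussian carries >95% of its mass.
    """

    sigma_d: float = 1.8
    sigma_r: float = 0.1
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_d <= 0:
            raise ValueError(f"sigma_d must be > 0, got {self.sigma_d}")
        if self.sigma_r <= 0:
            raise ValueError(f"sigma_r must be > 0, got {self.sigma_r}")
        if self.radius is not None and self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")

    @property
    def window_radius(self) -> int:
        return self.radius if self.radius is not None else max(1, math.ceil(2 * self.sigma_d))


def bilateral_filter(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Filter a 2D grid; output has the same shape and lies within each
    pixel's local window min/max (convex combination of neighbors)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2D grid, got shape {img.shape}")
    r = params.window_radius
    padded = np.pad(img, r, mode="symmetric")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv2sd = 1.0 / (2.0 * params.sigma_d**2)
    inv2sr = 1.0 / (2.0 * params.sigma_r**2)
    h, w = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = math.exp(-(dy * dy + dx * dx) * inv2sd) * np.exp(
                -((img - shifted) ** 2) * inv2sr
            )
            num += shifted * wgt
            den += wgt
    return num / den
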