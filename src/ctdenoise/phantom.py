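"""Analytic Shepp-Logan head phantom.

The phantom is the standard synthetic test object for CT algorithms: ten
ellipses with fixed centres, semi-axes, tilt angles and additive intensities,
rendered on a square grid over the unit disc coordinate frame [-1, 1]^2.
The "modified" intensity table is used (high-contrast variant, the same one
MATLAB's ``phantom`` and scikit-image ship), so tissue detail is visible
without windowing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_shepp_logan", "SHEPP_LOGAN_ELLIPSES"]

# Columns: additive intensity A, semi-axis a (x), semi-axis b (y),
# centre x0, centre y0, rotation angle phi in degrees (counter-clockwise).
SHEPP_LOGAN_ELLIPSES: np.ndarray = np.array(
    [
        [1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0],
        [-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0],
        [-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0],
        [-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0],
        [0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0],
        [0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0],
        [0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0],
        [0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0],
    ]
)


def ellipse_mask(size: int, ellipse: np.ndarray) -> np.ndarray:
    """Boolean membership mask of one phantom ellipse on a size x size grid."""
    _, a, b, x0, y0, phi_deg = ellipse
    x = np.linspace(-1.0, 1.0, size)
    y = np.linspace(1.0, -1.0, size)  # row 0 is the top of the head
    xx, yy = np.meshgrid(x, y)
    phi = np.deg2rad(phi_deg)
    xr = (xx - x0) * np.cos(phi) + (yy - y0) * np.sin(phi)
    yr = -(xx - x0) * np.sin(phi) + (yy - y0) * np.cos(phi)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def generate_shepp_logan(size: int = 512) -> np.ndarray:
    """Render the modified Shepp-Logan phantom as a float image in [0, 1].

    Parameters
    ----------
    size : int
        Edge length in pixels of the square output grid. Must be >= 8 so
        that at least one wavelet decomposition level is feasible.

    Returns
    -------
    numpy.ndarray
        ``(size, size)`` float64 array, linearly rescaled so the rendered
        intensities span exactly [0, 1].
    """
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    img = np.zeros((size, size), dtype=np.float64)
    for ellipse in SHEPP_LOGAN_ELLIPSES:
        img[ellipse_mask(size, ellipse)] += ellipse[0]
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img
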