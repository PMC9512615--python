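"""Multilevel 2D discrete wavelet analysis and coefficient shrinkage.

The separable 2D DWT (rows filtered and decimated first, then columns)
splits an image into an approximation band cA plus horizontal/vertical/
diagonal detail bands (cH, cV, cD) per level; the cascade recurses on cA.
PyWavelets performs the filter-bank arithmetic; this module owns the
decomposition container, the shrinkage (thresholding) function family and
the threshold selectors.

Shrinkage maps, applied elementwise to a detail coefficient w with
threshold lam >= 0 and adjustment coefficient a in [0, 1]:

* ``hard``        : keep w where |w| >= lam, else 0;
* ``soft``        : sign(w) * (|w| - lam) where |w| >= lam, else 0;
* ``compromise``  : sign(w) * (|w| - a*lam) where |w| >= lam, else 0
  (a=1 reduces to soft, a=0 to hard);
* ``improved``    : sign(w) * (|w| - (1-a)*lam) where |w| >= lam, else a*w
  (a=0 reduces to soft); the small-coefficient branch attenuates rather
  than zeroes, retaining part of the weak signal that classic thresholds
  discard. A literal variant replacing small coefficients with the
  constant a*lam is available behind ``small_branch="constant"``.

Threshold selectors:

* universal (fixed) threshold ``T = sigma * sqrt(2 ln N)``;
* BayesShrink per-subband threshold ``T = sigma^2 / sigma_x`` with the
  signal scale ``sigma_x = sqrt(max(E[w^2] - sigma^2, 0))``;
* a manual user-supplied lambda.

The noise scale sigma is estimated robustly from the finest diagonal
subband as ``median(|cD1|) / 0.674`` (median absolute deviation of a
zero-mean Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "ShrinkageRule",
    "decompose",
    "reconstruct",
    "shrink",
    "estimate_sigma",
    "estimate_noise_sigma",
    "universal_threshold",
    "bayes_threshold",
    "shrink_decomposition",
]

MAD_GAUSSIAN_SCALE = 0.674  # median(|N(0,1)|); threshold selectors divide by it

_MODES = ("hard", "soft", "compromise", "improved")
_SELECTORS = ("fixed_universal", "bayes", "manual")


@dataclass
class WaveletDecomposition:
    """Approximation band plus per-level detail triples of a 2D DWT.

    ``details`` is ordered finest (level 1) to coarsest (level L); each
    entry is the ``(cH, cV, cD)`` triple of that level.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    boundary_mode: str
    original_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.details)

    def finest_diagonal(self) -> np.ndarray:
        return self.details[0][2]

    def map_details(self, fn) -> "WaveletDecomposition":
        """Return a copy with ``fn(subband, level)`` applied to every detail band."""
        new = [tuple(fn(band, lvl + 1) for band in triple)
               for lvl, triple in enumerate(self.details)]
        return replace(self, approximation=self.approximation.copy(), details=new)


@dataclass(frozen=True)
class ShrinkageRule:
    """Shrinkage mode, adjustment coefficient and threshold selector."""

    mode: str = "improved"
    a: float = 0.5
    selector: str = "bayes"
    manual_lambda: float = 0.0
    small_branch: str = "scale_coeff"  # improved mode only: "scale_coeff" | "constant"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown shrinkage mode {self.mode!r}; expected one of {_MODES}")
        if self.selector not in _SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}; expected one of {_SELECTORS}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"adjustment coefficient a must lie in [0, 1], got {self.a}")
        if self.manual_lambda < 0:
            raise ValueError(f"manual_lambda must be >= 0, got {self.manual_lambda}")
        if self.small_branch not in ("scale_coeff", "constant"):
            raise ValueError(f"unknown small_branch {self.small_branch!r}")


def decompose(
    img: np.ndarray,
    wavelet_name: str = "db4",
    levels: int = 3,
    boundary_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Cascaded separable 2D DWT of ``img`` down to ``levels`` scales."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwtn_max_level(img.shape, wavelet)
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if levels > max_level:
        raise ValueError(
            f"levels={levels} is too deep for shape {img.shape} with wavelet "
            f"{wavelet_name!r}; maximum feasible level is {max_level}"
        )
    coeffs = pywt.wavedec2(img, wavelet, mode=boundary_mode, level=levels)
    # wavedec2 orders coarsest-first; store finest-first.
    details = [tuple(np.asarray(b) for b in triple) for triple in coeffs[:0:-1]]
    return WaveletDecomposition(
        approximation=np.asarray(coeffs[0]),
        details=details,
        wavelet_name=wavelet_name,
        boundary_mode=boundary_mode,
        original_shape=img.shape,
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse cascade; output cropped to the original shape, not clipped."""
    for lvl, triple in enumerate(dec.details):
        shapes = {b.shape for b in triple}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent subband shapes at level {lvl + 1}: {shapes}")
    coeffs = [dec.approximation] + [tuple(t) for t in dec.details[::-1]]
    out = pywt.waverec2(coeffs, pywt.Wavelet(dec.wavelet_name), mode=dec.boundary_mode)
    h, w = dec.original_shape
    return out[:h, :w]


def shrink(w, lam: float, rule: ShrinkageRule):
    """Apply the rule's shrinkage map elementwise; works on scalars or arrays."""
    if lam < 0:
        raise ValueError(f"threshold must be >= 0, got {lam}")
    w = np.asarray(w, dtype=np.float64)
    absw = np.abs(w)
    sgn = np.sign(w)
    keep = absw >= lam
    if rule.mode == "hard":
        out = np.where(keep, w, 0.0)
    elif rule.mode == "soft":
        out = np.where(keep, sgn * (absw - lam), 0.0)
    elif rule.mode == "compromise":
        out = np.where(keep, sgn * (absw - rule.a * lam), 0.0)
    else:  # improved
        big = sgn * (absw - (1.0 - rule.a) * lam)
        small = rule.a * w if rule.small_branch == "scale_coeff" else np.full_like(w, rule.a * lam)
        out = np.where(keep, big, small)
    return out if out.ndim else float(out)


def estimate_sigma(finest_diagonal: np.ndarray) -> float:
    """Robust noise-scale estimate ``median(|cD1|) / 0.674``."""
    d = np.asarray(finest_diagonal, dtype=np.float64)
    if d.size == 0:
        raise ValueError("cannot estimate sigma from an empty coefficient grid")
    return float(np.median(np.abs(d)) / MAD_GAUSSIAN_SCALE)


def estimate_noise_sigma(img: np.ndarray, wavelet_name: str = "db4") -> float:
    """Noise sigma of an image, via the MAD of its finest diagonal subband."""
    dec = decompose(img, wavelet_name=wavelet_name, levels=1)
    return estimate_sigma(dec.finest_diagonal())


def universal_threshold(sigma: float, n_coeffs: int) -> float:
    """Donoho's fixed threshold ``sigma * sqrt(2 ln N)`` (natural log)."""
    if n_coeffs < 1:
        raise ValueError(f"n_coeffs must be >= 1, got {n_coeffs}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    return float(sigma * np.sqrt(2.0 * np.log(n_coeffs)))


def bayes_threshold(subband: np.ndarray, sigma: float) -> float:
    """BayesShrink subband threshold ``sigma^2 / sigma_x``.

    The clean-signal scale is ``sigma_x = sqrt(max(E[w^2] - sigma^2, 0))``.
    When no signal variance is detected (``sigma_x = 0``) the threshold is
    ``max |w|``, which suppresses the whole subband.
    """
    w = np.asarray(subband, dtype=np.float64)
    if w.size == 0:
        raise ValueError("cannot select a threshold for an empty subband")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    sigma_x = np.sqrt(max(np.mean(w * w) - sigma * sigma, 0.0))
    if sigma_x == 0.0:
        return float(np.max(np.abs(w)))
    return float(sigma * sigma / sigma_x)


def _select_lambda(subband: np.ndarray, sigma: float, rule: ShrinkageRule) -> float:
    if rule.selector == "manual":
        return rule.manual_lambda
    if rule.selector == "fixed_universal":
        return universal_threshold(sigma, subband.size)
    return bayes_threshold(subband, sigma)


def shrink_decomposition(
    dec: WaveletDecomposition,
    rule: ShrinkageRule,
    sigma: float | None = None,
) -> WaveletDecomposition:
    """Shrink every detail subband, choosing lambda per subband by the selector.

    The approximation band is left untouched. ``sigma`` is estimated once
    from the finest diagonal band when not supplied.
    """
    if sigma is None:
        sigma = estimate_sigma(dec.finest_diagonal())
    return dec.map_details(lambda band, lvl: shrink(band, _select_lambda(band, sigma, rule), rule))
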