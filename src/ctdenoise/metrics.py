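"""Full-reference image quality metrics: MSE, PSNR, SSIM.

All metrics assume the [0, 1] intensity convention, so the PSNR peak
defaults to 1.0 and the SSIM stability constants are C1 = (0.01)^2 and
C2 = (0.03)^2. SSIM uses the canonical configuration: an 11x11 Gaussian
weighting window with sigma 1.5 and population (not sample) statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "mse", "psnr", "ssim", "evaluate"]

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape} vs test {test.shape}")
    return ref, test


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared difference over all pixels (intensity^2 units)."""
    ref, test = _check_pair(ref, test)
    return float(np.mean((ref - test) ** 2))


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in dB.

    Returns ``inf`` for identical images (MSE = 0).
    """
    err = mse(ref, test)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / err))


def ssim(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Mean structural similarity index in [-1, 1]."""
    ref, test = _check_pair(ref, test)
    if min(ref.shape) < SSIM_WINDOW:
        raise ValueError(
            f"image minimum dimension {min(ref.shape)} is smaller than the "
            f"{SSIM_WINDOW}x{SSIM_WINDOW} SSIM window"
        )
    return float(
        structural_similarity(
            ref,
            test,
            data_range=peak,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            use_sample_covariance=False,
        )
    )


@dataclass(frozen=True)
class QualityReport:
    """MSE / PSNR / SSIM of a test image against a reference."""

    mse: float
    psnr: float
    ssim: float

    def to_json(self) -> str:
        d = {"mse": self.mse, "psnr": self.psnr, "ssim": self.ssim}
        if np.isinf(self.psnr):
            d["psnr"] = "inf"
        return json.dumps(d)


def evaluate(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> QualityReport:
    """All three metrics at once."""
    return QualityReport(
        mse=mse(ref, test), psnr=psnr(ref, test, peak), ssim=ssim(ref, test, peak)
    )
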