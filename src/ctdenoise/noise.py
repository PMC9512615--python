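"""Seeded noise models for CT image simulation.

Three degradation models are provided, all operating on images with
intensities on the [0, 1] scale:

* additive Gaussian noise  ``g = clip(x + n)``, ``n ~ N(mean, variance)``;
* impulse (salt-and-pepper) noise — a fraction ``density`` of pixels is
  replaced, half by the bright extreme 1.0 (salt) and half by the dark
  extreme 0.0 (pepper);
* multiplicative speckle noise  ``g = clip(x * (1 + n))`` with zero-mean
  Gaussian ``n``.

Every injector is deterministic given the :class:`NoiseSpec` (including its
seed) and preserves the input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSpec",
    "add_gaussian_noise",
    "add_salt_pepper_noise",
    "add_speckle_noise",
    "add_noise",
]

_KINDS = ("gaussian", "salt_pepper", "speckle")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise kind plus the parameters relevant to it.

    ``mean``/``variance`` apply to gaussian, ``variance`` to speckle, and
    ``density`` (fraction of corrupted pixels) to salt_pepper; parameters
    irrelevant to ``kind`` are ignored.
    """

    kind: str
    mean: float = 0.0
    variance: float | None = None
    density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind in ("gaussian", "speckle"):
            if self.variance is None:
                raise ValueError(f"{self.kind} noise requires a variance")
            if self.variance < 0:
                raise ValueError(f"variance must be >= 0, got {self.variance}")
        if self.kind == "salt_pepper":
            if self.density is None:
                raise ValueError("salt_pepper noise requires a density")
            if not 0.0 <= self.density <= 1.0:
                raise ValueError(f"density must lie in [0, 1], got {self.density}")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    return img


def add_gaussian_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Additive zero- or nonzero-mean Gaussian noise, clipped to [0, 1]."""
    img = _check_image(img)
    if spec.kind != "gaussian":
        raise ValueError(f"spec.kind must be 'gaussian', got {spec.kind!r}")
    if spec.variance == 0:
        return img + spec.mean if spec.mean else img.copy()
    rng = np.random.default_rng(spec.seed)
    n = rng.normal(spec.mean, np.sqrt(spec.variance), size=img.shape)
    return np.clip(img + n, 0.0, 1.0)


def add_salt_pepper_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Impulse noise: ``density * n_pixels`` sites (drawn without replacement)
    are overwritten, the rounded half with salt (1.0), the rest with pepper (0.0)."""
    img = _check_image(img)
    if spec.kind != "salt_pepper":
        raise ValueError(f"spec.kind must be 'salt_pepper', got {spec.kind!r}")
    out = img.copy()
    n_pixels = img.size
    n_corrupt = int(round(spec.density * n_pixels))
    if n_corrupt == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    sites = rng.choice(n_pixels, size=n_corrupt, replace=False)
    n_salt = int(np.floor(n_corrupt / 2 + 0.5))
    flat = out.reshape(-1)
    flat[sites[:n_salt]] = 1.0
    flat[sites[n_salt:]] = 0.0
    return out


def add_speckle_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Multiplicative speckle noise ``g = x * (1 + n)``, clipped to [0, 1]."""
    img = _check_image(img)
    if spec.kind != "speckle":
        raise ValueError(f"spec.kind must be 'speckle', got {spec.kind!r}")
    if spec.variance == 0:
        return img.copy()
    rng = np.random.default_rng(spec.seed)
    n = rng.normal(0.0, np.sqrt(spec.variance), size=img.shape)
    return np.clip(img * (1.0 + n), 0.0, 1.0)


def add_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Dispatch to the injector matching ``spec.kind``."""
    if spec.kind == "gaussian":
        return add_gaussian_noise(img, spec)
    if spec.kind == "salt_pepper":
        return add_salt_pepper_noise(img, spec)
    return add_speckle_noise(img, spec)
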