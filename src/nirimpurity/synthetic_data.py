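"""Seeded synthetic NIR reflectance datasets for pipeline testing.

Spectra are generated reflectance-native: a smooth base continuum plus
Gaussian absorption bands whose depths scale linearly with the per-sample
impurity fraction, then corrupted by multiplicative scatter, additive
baseline offset, and white noise:

    clean_i  = base + sum_b loading_b * y_i * exp(-(wl - center_b)^2 / (2 width_b^2))
    observed = a_i * clean_i + c_i + noise,   a_i ~ N(1, scatter_sd), c_i ~ N(0, baseline_sd)

With all corruption set to zero, every channel inside a band is an exact
affine function of y, and SNV removes the (a_i, c_i) pair exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectraSet

__all__ = ["SyntheticConfig", "generate_dataset"]

#: (center nm, width nm, loading) — negative loadings are absorption dips
DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (1200.0, 30.0, -0.9),
    (1450.0, 45.0, -1.2),
    (1590.0, 25.0, -0.6),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 230
    n_channels: int = 125
    wavelength_range: tuple[float, float] = (950.0, 1650.0)
    target_range: tuple[float, float] = (0.03, 0.20)
    informative_bands: tuple[tuple[float, float, float], ...] = DEFAULT_BANDS
    scatter_sd: float = 0.05
    baseline_sd: float = 0.02
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need n_samples >= 4")
        if self.n_channels < 2:
            raise ValueError("need n_channels >= 2")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength_range must be increasing")
        for c, w, _ in self.informative_bands:
            if not lo <= c <= hi:
                raise ValueError(f"band center {c} nm outside wavelength range [{lo}, {hi}]")
            if w <= 0:
                raise ValueError("band widths must be positive")
        if min(self.scatter_sd, self.baseline_sd, self.noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _base_continuum(wl: np.ndarray) -> np.ndarray:
    """Smooth sample-independent reflectance background in roughly [0.5, 0.75]."""
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.65 - 0.08 * t + 0.05 * np.exp(-((t - 0.35) ** 2) / (2 * 0.18**2))


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectraSet, np.ndarray]:
    """Generate a seeded dataset; returns (SpectraSet, informative channel indices).

    The ground-truth indices are the channels where some band's Gaussian
    weight is at least half its peak (FWHM overlap).
    """
    rng = np.random.default_rng(cfg.seed)
    wl = np.linspace(*cfg.wavelength_range, cfg.n_channels)
    y = rng.uniform(*cfg.target_range, size=cfg.n_samples)

    base = _base_continuum(wl)
    band_profile = np.zeros_like(wl)  # sum_b loading_b * gaussian_b, per channel
    informative = np.zeros_like(wl, dtype=bool)
    for center, width, loading in cfg.informative_bands:
        g = np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        band_profile += loading * g
        informative |= g >= 0.5

    clean = base[None, :] + y[:, None] * band_profile[None, :]
    a = rng.normal(1.0, cfg.scatter_sd, size=cfg.n_samples)
    c = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_samples)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_channels))
    observed = a[:, None] * clean + c[:, None] + noise
    observed = np.clip(observed, 0.0, None)  # reflectance is non-negative

    data = SpectraSet(
        wavelengths=wl,
        reflectance=observed,
        target=y,
        sample_ids=tuple(f"s{i:04d}" for i in range(cfg.n_samples)),
    )
    return data, np.flatnonzero(informative)
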