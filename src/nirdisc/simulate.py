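"""Synthetic NIR spectra with class-dependent absorption bands.

The generator emulates diffuse-reflectance NIR spectra of stored leafy
vegetables: a handful of Gaussian absorption bands whose amplitudes decay
with storage time (water loss around 5100 cm^-1, protein degradation in the
6000–7000 cm^-1 overtone region), distorted by the artifacts scatter
correction is meant to remove — a per-sample multiplicative gain, a linear
baseline drift, a constant offset, and white noise.

The clean class-c spectrum is

    s_c(nu) = sum_b A_b * (1 - r_b)^c * exp(-(nu - c_b)^2 / (2 w_b^2))

and the observed spectrum of sample i in class c is

    x_i(nu) = g_i * s_c(nu) + m_i * (nu - nu_0)/1000 + o_i + eps_i(nu)

with g_i ~ 1 + N(0, gain_sd), m_i ~ N(0, drift_sd), o_i ~ N(0, offset_sd)
and eps ~ N(0, noise_sd) i.i.d. per point.  All draws come from a single
seeded stream consumed in a documented order (gains, slopes, offsets,
noise), so identical configs produce bit-identical output.

With the default design (5 classes x 60 samples, 1577 grid points) the
feature dimension far exceeds any training-fold size, so the within-class
scatter matrix of a training fold is singular — the small-sample-size
regime the discriminant extractors in :mod:`nirdisc.sss_lda` target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from nirdisc.spectra import SpectraSet

__all__ = ["BandSpec", "SyntheticConfig", "default_config", "generate"]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band with a per-class amplitude decay.

    ``class_decay`` is the fractional amplitude loss per storage step: class
    c sees amplitude ``base_amplitude * (1 - class_decay)**c``.
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    base_amplitude: float  # absorbance units
    class_decay: float = 0.0  # in [0, 1)

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if not 0.0 <= self.class_decay < 1.0:
            raise ValueError(f"class_decay must be in [0, 1), got {self.class_decay}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic acquisition campaign."""

    n_classes: int
    samples_per_class: int
    grid_start: float  # cm^-1
    grid_spacing: float  # cm^-1
    grid_points: int
    bands: tuple[BandSpec, ...]
    gain_sd: float  # multiplicative scatter SD (unitless)
    offset_sd: float  # additive offset SD (absorbance)
    drift_sd: float  # SD of baseline slope per 1000 cm^-1
    noise_sd: float  # per-point additive noise SD (absorbance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1 or self.grid_points < 1:
            raise ValueError("n_classes, samples_per_class, grid_points must be >= 1")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be positive")
        for name in ("gain_sd", "offset_sd", "drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid_start + self.grid_spacing * np.arange(self.grid_points)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def default_config() -> SyntheticConfig:
    """The default storage-time study design.

    Five storage-time classes (0h..24h in 6 h steps) with 60 spectra each
    — 300 spectra of 1577 points on a grid starting at 4000 cm^-1 with
    3.856 cm^-1 spacing.  Two absorption bands decay with storage: a strong
    water combination band near 5100 cm^-1 and a weaker N-H overtone band
    near 6500 cm^-1.  Scatter-artifact magnitudes are chosen so that the
    per-sample gain spread dominates the per-step class signal in the raw
    spectra (scatter correction is genuinely needed) while the per-point
    noise stays small against the class signal.
    """
    return SyntheticConfig(
        n_classes=5,
        samples_per_class=60,
        grid_start=4000.0,
        grid_spacing=3.856,
        grid_points=1577,
        bands=(
            BandSpec(center=5100.0, width=160.0, base_amplitude=1.0, class_decay=0.10),
            BandSpec(center=6500.0, width=280.0, base_amplitude=0.55, class_decay=0.06),
        ),
        gain_sd=0.15,
        offset_sd=0.05,
        drift_sd=0.03,
        noise_sd=0.003,
        seed=12345,
    )


def class_label(c: int) -> str:
    """Storage-time name for class index c: 0 -> "0h", 1 -> "6h", ..."""
    return f"{6 * c}h"


def clean_class_spectrum(config: SyntheticConfig, c: int) -> np.ndarray:
    """Noise-free spectrum of class ``c`` (the generator's analytic mean)."""
    nu = config.wavenumbers
    out = np.zeros_like(nu)
    for b in config.bands:
        amp = b.base_amplitude * (1.0 - b.class_decay) ** c
        out += amp * np.exp(-((nu - b.center) ** 2) / (2.0 * b.width**2))
    return out


def generate(config: SyntheticConfig) -> SpectraSet:
    """Draw one labeled SpectraSet from the configured model.

    Samples are ordered class-major (all class 0, then class 1, ...).  The
    seeded stream is consumed as: all gains, all slopes, all offsets, then
    the noise matrix — refactoring-stable determinism.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_classes * config.samples_per_class
    p = config.grid_points
    nu = config.wavenumbers

    gains = 1.0 + rng.normal(0.0, config.gain_sd, size=n)
    slopes = rng.normal(0.0, config.drift_sd, size=n)
    offsets = rng.normal(0.0, config.offset_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))

    ramp = (nu - config.grid_start) / 1000.0
    clean = np.stack(
        [clean_class_spectrum(config, c) for c in range(config.n_classes)]
    )
    class_of = np.repeat(np.arange(config.n_classes), config.samples_per_class)

    absorbance = (
        gains[:, None] * clean[class_of]
        + slopes[:, None] * ramp[None, :]
        + offsets[:, None]
        + noise
    )
    labels = np.array([class_label(c) for c in class_of], dtype=object)
    sample_ids = np.array(
        [
            f"{class_label(c)}_{i:03d}"
            for c in range(config.n_classes)
            for i in range(config.samples_per_class)
        ],
        dtype=object,
    )
    return SpectraSet(
        wavenumbers=nu, absorbance=absorbance, labels=labels, sample_ids=sample_ids
    )
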