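"""Synthetic hyperspectral scenes and labeled spectral datasets.

Emulates a laboratory grape-cluster residue experiment: two push-broom
instruments (a Vis-NIR grid of 80 bands over 476-890 nm and a NIR grid of
230 bands over 970-1594 nm), three grape varieties, and four pesticide-residue
levels (level 0 = distilled water control). The generative model for a berry
spectrum is

    x(lambda) = g * [ b_v(lambda) - d_level * p(lambda) ] + o + eps(lambda)

where ``b_v`` is a smooth variety-specific base reflectance curve,
``p`` is a sum of narrow Gaussian absorption peaks at a few designated
*informative* wavelengths, ``d_level`` is a class-ordered peak depth,
``g ~ N(1, scatter_sd)`` is a per-sample multiplicative scatter gain,
``o ~ N(0, baseline_sd)`` a per-sample additive baseline, and ``eps`` i.i.d.
per-band noise. The multiplicative+additive corruption is exactly the model
that the standard normal variate transform removes, and the class signal is
deliberately small relative to scatter so raw spectra overlap heavily across
levels, as real residue spectra do.

Scene mode additionally renders the spectrum into a raw digital-number cube by
inverting the flat-field reflectance correction against synthetic white/dark
reference frames, so the correction stage can be tested against an exact
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import VARIETIES, SpectralDataset

#: per-variety sample counts for levels 0..3 (column totals 254/261/271/285,
#: grand total 1071 clusters)
DEFAULT_CLASS_COUNTS: Mapping[str, tuple[int, ...]] = {
    "Cabernet": (73, 84, 60, 71),
    "Red": (92, 99, 107, 113),
    "Munage": (89, 78, 104, 101),
}

VISNIR_GRID = np.linspace(476.0, 890.0, 80)    # reserved Vis-NIR range
NIR_GRID = np.linspace(970.0, 1594.0, 230)     # reserved NIR range
VISNIR_FULL_GRID = np.linspace(376.0, 1044.0, 128)  # instrument-native
NIR_FULL_GRID = np.linspace(915.0, 1699.0, 288)     # instrument-native


def default_base_curve(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth berry-like reflectance base in (0, 1) on any grid in 376-1699 nm.

    Low visible reflectance with a green bump near 550 nm, a red edge around
    700 nm, and broad water-related absorption dips near 970 and 1450 nm.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    curve = (
        0.30
        + 0.30 / (1.0 + np.exp(-(wl - 700.0) / 40.0))
        + 0.08 * np.exp(-((wl - 550.0) ** 2) / (2 * 35.0**2))
        - 0.10 * np.exp(-((wl - 970.0) ** 2) / (2 * 45.0**2))
        - 0.14 * np.exp(-((wl - 1450.0) ** 2) / (2 * 70.0**2))
    )
    return curve


def _default_peak_centers(wl: np.ndarray) -> tuple[float, ...]:
    """Three informative wavelengths for the given grid (Vis-NIR or NIR)."""
    if wl[-1] <= 1050.0:
        return (530.0, 670.0, 810.0)
    return (1120.0, 1300.0, 1450.0)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SceneConfig:
    """All parameters of the synthetic generator.

    Defaults reproduce the study design: Vis-NIR 80-band grid, 4 residue
    levels with the per-variety cluster counts of the source experiment,
    class peak depths 0.00/0.02/0.04/0.08 reflectance units at three
    informative bands, scatter sd 0.15, baseline sd 0.05, band noise sd 0.01.
    """

    wavelength_grid: np.ndarray = field(default_factory=lambda: VISNIR_GRID.copy())
    n_classes: int = 4
    class_counts: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CLASS_COUNTS.items()}
    )
    peak_centers: tuple[float, ...] | None = None
    peak_depths: tuple[float, ...] = (0.00, 0.02, 0.04, 0.08)
    peak_width_nm: float = 14.0
    scatter_sd: float = 0.15
    baseline_sd: float = 0.05
    noise_sd: float = 0.01
    berry_reflectance_base: np.ndarray | None = None
    variety_shift_scale: float = 0.02
    background_reflectance: float = 0.05
    image_shape: tuple[int, int] = (64, 64)
    berry_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.wavelength_grid.ndim != 1 or self.wavelength_grid.size < 2:
            raise ConfigError("wavelength_grid must be a 1-D grid of >= 2 bands")
        if not np.all(np.diff(self.wavelength_grid) > 0):
            raise ConfigError("wavelength_grid must be strictly increasing")
        if self.peak_centers is None:
            self.peak_centers = _default_peak_centers(self.wavelength_grid)
        for name in ("scatter_sd", "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.peak_depths) != self.n_classes:
            raise ConfigError("peak_depths must have one entry per class")
        # nondecreasing; all-equal depths are the null model (no class signal)
        if np.any(np.diff(self.peak_depths) < 0):
            raise ConfigError("peak_depths must be nondecreasing with level")
        if self.berry_reflectance_base is None:
            self.berry_reflectance_base = default_base_curve(self.wavelength_grid)
        self.berry_reflectance_base = np.asarray(self.berry_reflectance_base, float)
        if self.berry_reflectance_base.shape != self.wavelength_grid.shape:
            raise ConfigError("base curve must match the wavelength grid")
        if not np.all((self.berry_reflectance_base > 0) & (self.berry_reflectance_base < 1)):
            raise ConfigError("base curve values must lie in (0, 1)")
        if not 0.0 < self.berry_fraction < 1.0:
            raise ConfigError("berry_fraction must lie in (0, 1)")
        if min(self.image_shape) < 4:
            raise ConfigError("image_shape too small")

    @property
    def n_bands(self) -> int:
        return self.wavelength_grid.size

    def informative_band_indices(self) -> np.ndarray:
        """Grid indices nearest the designated informative wavelengths."""
        return np.array(
            [int(np.argmin(np.abs(self.wavelength_grid - c))) for c in self.peak_centers]
        )

    def peak_profile(self) -> np.ndarray:
        """Unit-depth absorption profile: sum of Gaussians at the peak centers."""
        wl = self.wavelength_grid
        prof = np.zeros_like(wl)
        for c in self.peak_centers:
            prof += np.exp(-((wl - c) ** 2) / (2 * self.peak_width_nm**2))
        return prof

    def variety_shift(self, variety: str) -> np.ndarray:
        """Smooth variety-specific offset of the base curve (no level interaction).

        Cabernet is the zero-shift reference, so the default scene's berry
        reflectance equals the base curve exactly when randomness is off.
        """
        coeff = {"Cabernet": 0.0, "Red": 1.0, "Munage": -1.0}[variety]
        wl = self.wavelength_grid
        span = wl[-1] - wl[0]
        center = wl[0] + span * (0.3 + 0.2 * VARIETIES.index(variety))
        return self.variety_shift_scale * coeff * np.exp(
            -((wl - center) ** 2) / (2 * (span / 4.0) ** 2)
        )

    def class_mean_spectrum(self, level: int, variety: str = "Cabernet") -> np.ndarray:
        """Noise-free expected reflectance spectrum for (level, variety)."""
        if not 0 <= level < self.n_classes:
            raise ValueError(f"level must be in [0, {self.n_classes})")
        return (
            self.berry_reflectance_base
            + self.variety_shift(variety)
            - self.peak_depths[level] * self.peak_profile()
        )


@dataclass
class RawScene:
    """One synthetic sub-image: raw digital numbers plus reference frames.

    ``truth_reflectance`` and ``truth_mask`` carry the generator's ground
    truth for testing the correction and segmentation stages.
    """

    raw_cube: np.ndarray
    white_cube: np.ndarray
    dark_cube: np.ndarray
    truth_mask: np.ndarray
    truth_reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    level: int
    variety: str

    def __post_init__(self) -> None:
        if not (self.raw_cube.shape == self.white_cube.shape == self.dark_cube.shape):
            raise ValueError("raw/white/dark cubes must share a shape")
        if self.raw_cube.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band axis must match the wavelength grid")
        if not np.all(self.white_cube > self.dark_cube):
            raise ValueError("white reference must exceed dark reference")
        if not self.truth_mask.any():
            raise ValueError("truth_mask must contain berry pixels")


def _reference_frames(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """White/dark digital-number frames with small fixed spatial gradients.

    The gradients make the correction non-trivial (dividing by a constant
    would also pass a flat-field test); they are deterministic functions of
    the geometry, not random.
    """
    rows, cols = config.image_shape
    wl = config.wavelength_grid
    r = np.linspace(-1.0, 1.0, rows)[:, None, None]
    c = np.linspace(-1.0, 1.0, cols)[None, :, None]
    lamp = 0.75 + 0.25 * np.exp(-((wl - 0.5 * (wl[0] + wl[-1])) ** 2)
                                / (2 * (0.6 * (wl[-1] - wl[0])) ** 2))
    white = 4000.0 * lamp[None, None, :] * (1.0 + 0.05 * r + 0.02 * c)
    dark = 120.0 * (1.0 + 0.03 * c - 0.01 * r) * np.ones_like(white)
    return white, dark


def _sample_spectra(config: SceneConfig, level: int, variety: str, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw n berry spectra from the generative model (scatter, baseline, noise)."""
    clean = config.class_mean_spectrum(level, variety)
    gain = 1.0 + config.scatter_sd * rng.standard_normal(n)
    offset = config.baseline_sd * rng.standard_normal(n)
    noise = config.noise_sd * rng.standard_normal((n, config.n_bands))
    return gain[:, None] * clean[None, :] + offset[:, None] + noise


def generate_scene(config: SceneConfig, level: int, seed: int,
                   variety: str = "Cabernet") -> RawScene:
    """Render one labeled sub-image as raw/white/dark digital-number cubes.

    Berry pixels share one per-scene scatter gain and baseline offset (a
    cluster is one physical sample) and carry independent per-pixel band
    noise; background pixels are a flat low-reflectance panel. Raw counts are
    produced by the exact inverse of the flat-field correction,
    ``raw = R * (white - dark) + dark``, so correction recovers the
    reflectance field exactly when noise is off.
    """
    if not 0 <= level < config.n_classes:
        raise ValueError(f"level must be in [0, {config.n_classes})")
    if variety not in VARIETIES:
        raise ValueError(f"unknown variety {variety!r}")
    rng = np.random.default_rng([config.seed, level, seed])
    rows, cols = config.image_shape

    # elliptical berry-cluster mask with jittered center and radius whose
    # expected area fraction equals berry_fraction
    r0 = np.sqrt(config.berry_fraction * rows * cols / np.pi)
    radius = r0 * (1.0 + 0.08 * rng.uniform(-1, 1))
    cy = rows / 2.0 + 0.08 * rows * rng.uniform(-1, 1)
    cx = cols / 2.0 + 0.08 * cols * rng.uniform(-1, 1)
    yy, xx = np.mgrid[0:rows, 0:cols]
    stretch = 1.0 + 0.15 * rng.uniform(-1, 1)
    mask = (((yy - cy) * stretch) ** 2 + ((xx - cx) / stretch) ** 2) <= radius**2
    if not mask.any():
        mask[rows // 2, cols // 2] = True

    clean = config.class_mean_spectrum(level, variety)
    gain = 1.0 + config.scatter_sd * rng.standard_normal()
    offset = config.baseline_sd * rng.standard_normal()
    reflectance = np.broadcast_to(
        np.float64(config.background_reflectance), (rows, cols, config.n_bands)
    ).copy()
    berry = gain * clean[None, :] + offset
    noise = config.noise_sd * rng.standard_normal((int(mask.sum()), config.n_bands))
    reflectance[mask] = berry + noise

    white, dark = _reference_frames(config)
    raw = reflectance * (white - dark) + dark
    return RawScene(
        raw_cube=raw, white_cube=white, dark_cube=dark, truth_mask=mask,
        truth_reflectance=reflectance, wavelengths_nm=config.wavelength_grid,
        level=level, variety=variety,
    )


def generate_dataset(config: SceneConfig) -> SpectralDataset:
    """Emit per-sample mean spectra directly, bypassing the imaging step.

    Samples are drawn per (variety, level) cell of ``class_counts`` from the
    same generative model as scene berry pixels; reproducible under
    ``config.seed``.
    """
    if not config.class_counts or all(
        len(v) == 0 for v in config.class_counts.values()
    ):
        raise ConfigError("class_counts must be nonempty")
    rng = np.random.default_rng([config.seed, 0xDA7A])
    spectra, labels, varieties = [], [], []
    for variety in VARIETIES:
        counts = config.class_counts.get(variety, ())
        for level, n in enumerate(counts):
            if n <= 0:
                raise ConfigError("class_counts must be positive")
            spectra.append(_sample_spectra(config, level, variety, n, rng))
            labels.extend([level] * n)
            varieties.extend([variety] * n)
    return SpectralDataset(
        X=np.vstack(spectra),
        wavelengths_nm=config.wavelength_grid,
        y=np.array(labels),
        variety=np.array(varieties, dtype=object),
        provenance=f"synthetic(seed={config.seed}, bands={config.n_bands})",
    )


def visnir_config(**overrides) -> SceneConfig:
    """Default Vis-NIR study configuration (80 bands, 476-890 nm)."""
    return SceneConfig(wavelength_grid=VISNIR_GRID.copy(), **overrides)


def nir_config(**overrides) -> SceneConfig:
    """Default NIR study configuration (230 bands, 970-1594 nm)."""
    return SceneConfig(wavelength_grid=NIR_GRID.copy(), **overrides)
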