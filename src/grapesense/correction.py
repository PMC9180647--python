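"""Flat-field reflectance correction, berry ROI segmentation, mean spectra.

Raw digital numbers are converted to reflectance with white and dark
reference frames,

    R = (I_raw - I_dark) / (I_white - I_dark),

the berry region of interest is segmented by thresholding a single
high-contrast band (804 nm for the Vis-NIR instrument, 1092 nm for NIR),
and the sample's spectrum is the per-band arithmetic mean over ROI pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .synthetic import RawScene

KINDS = ("raw", "reference_white", "reference_dark", "reflectance")


class DimensionError(ValueError):
    """Cube shapes or wavelength grids do not match."""


class DegenerateReferenceError(ValueError):
    """White and dark references coincide at some pixel-band."""


class SegmentationError(ValueError):
    """Thresholding produced no foreground."""


@dataclass
class SpectralCube:
    """A rows x cols x bands image stack with band-center metadata."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError("cube values must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise DimensionError("band axis must match wavelength grid length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DimensionError("wavelength grid must be strictly increasing")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance cube must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_index(self, band_nm: float) -> int:
        """Index of the grid band nearest ``band_nm`` (targets need not be on-grid)."""
        wl = self.wavelengths_nm
        if not wl[0] <= band_nm <= wl[-1]:
            raise ValueError(f"{band_nm} nm outside grid range [{wl[0]}, {wl[-1]}]")
        return int(np.argmin(np.abs(wl - band_nm)))


@dataclass
class RoiMask:
    """Boolean berry mask plus the band and threshold that produced it."""

    mask: np.ndarray
    band_used_nm: float
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise SegmentationError("ROI mask is empty")


def cubes_from_scene(scene: RawScene) -> tuple[SpectralCube, SpectralCube, SpectralCube]:
    """Wrap a synthetic scene's raw/white/dark arrays as typed cubes."""
    wl = scene.wavelengths_nm
    return (
        SpectralCube(scene.raw_cube, wl, "raw"),
        SpectralCube(scene.white_cube, wl, "reference_white"),
        SpectralCube(scene.dark_cube, wl, "reference_dark"),
    )


def correct_reflectance(raw: SpectralCube, white: SpectralCube,
                        dark: SpectralCube, gray_reference: bool = False) -> SpectralCube:
    """Convert raw counts to reflectance via the white/dark flat-field formula.

    With ``gray_reference=True`` the denominator uses a 50% gray panel,
    ``0.5*(white+dark) - dark``, and the result is rescaled by 0.5 — an
    alternative reading of calibrating against a half-intensity reference
    panel; algebraically identical to the default for ideal frames, kept as
    an explicit switch. Default is the plain formula.
    """
    for cube, kind in ((raw, "raw"), (white, "reference_white"), (dark, "reference_dark")):
        if cube.kind != kind:
            raise ValueError(f"expected a {kind} cube, got {cube.kind}")
    if not (raw.shape == white.shape == dark.shape):
        raise DimensionError("raw/white/dark cubes must share a shape")
    if not (np.array_equal(raw.wavelengths_nm, white.wavelengths_nm)
            and np.array_equal(raw.wavelengths_nm, dark.wavelengths_nm)):
        raise DimensionError("raw/white/dark cubes must share a wavelength grid")

    denom = white.values.astype(float) - dark.values.astype(float)
    bad = denom == 0
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateReferenceError(
            f"white == dark at (row, col, band) = {idx}"
        )
    if gray_reference:
        refl = 0.5 * (raw.values.astype(float) - dark.values) / (0.5 * denom)
    else:
        refl = (raw.values.astype(float) - dark.values) / denom
    return SpectralCube(refl, raw.wavelengths_nm, "reflectance")


def segment_roi(cube: SpectralCube, band_nm: float, method: str = "otsu",
                threshold: float | None = None, min_area: int = 20) -> RoiMask:
    """Threshold one band image into a berry mask; drop small components.

    ``method='otsu'`` derives the threshold from the band histogram;
    ``method='fixed'`` uses the supplied ``threshold``. Connected components
    smaller than ``min_area`` pixels are removed as speckle.
    """
    if cube.kind != "reflectance":
        raise ValueError("segmentation expects a reflectance cube")
    band = cube.values[:, :, cube.band_index(band_nm)]
    if method == "otsu":
        if np.ptp(band) == 0:
            raise SegmentationError("constant band image: no foreground to segment")
        thr = float(threshold_otsu(band))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    mask = band > thr
    if mask.any() and min_area > 1:
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise SegmentationError(
            f"no ROI pixels above threshold {thr:.4g} at {band_nm} nm after cleanup"
        )
    used_nm = float(cube.wavelengths_nm[cube.band_index(band_nm)])
    return RoiMask(mask=mask, band_used_nm=used_nm, threshold=thr)


def extract_mean_spectrum(cube: SpectralCube, roi: RoiMask) -> np.ndarray:
    """Per-band arithmetic mean of the cube over ROI pixels."""
    if roi.mask.shape != cube.values.shape[:2]:
        raise DimensionError("mask shape must match the cube's spatial shape")
    if not roi.mask.any():
        raise SegmentationError("ROI mask is empty")
    return cube.values[roi.mask].mean(axis=0)
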