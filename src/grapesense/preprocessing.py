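"""Spectral preprocessing: band trimming, Savitzky-Golay smoothing, SNV.

The pipeline order is trim -> SG -> SNV. All three transforms are
per-sample (row-wise), so preprocessing cannot leak information between
training and test samples.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset


class DegenerateSpectrumError(ValueError):
    """A spectrum is constant and cannot be SNV-scaled."""


def trim_bands(ds: SpectralDataset, lo_nm: float, hi_nm: float) -> SpectralDataset:
    """Keep bands with lo_nm <= center <= hi_nm (closed interval).

    Removes the noisy spectral ends; the study ranges are 476-890 nm
    (Vis-NIR) and 970-1594 nm (NIR).
    """
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    keep = (ds.wavelengths_nm >= lo_nm) & (ds.wavelengths_nm <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands retained in [{lo_nm}, {hi_nm}] nm")
    return SpectralDataset(
        X=ds.X[:, keep],
        wavelengths_nm=ds.wavelengths_nm[keep],
        y=ds.y,
        variety=ds.variety,
        provenance=ds.provenance + f"; trim[{lo_nm},{hi_nm}]",
    )


def sg_smooth(ds: SpectralDataset, window: int = 3, polyorder: int = 0) -> SpectralDataset:
    """Row-wise Savitzky-Golay smoothing (default polyorder 0, window 3).

    With polyorder 0 the filter reduces to a centered moving average of the
    window width. Edges use nearest-value padding so the band count is
    preserved.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > ds.n_bands:
        raise ValueError("window exceeds the number of bands")
    smoothed = savgol_filter(ds.X, window_length=window, polyorder=polyorder,
                             axis=1, mode="nearest")
    return ds.with_X(smoothed, note=f"sg(w={window},p={polyorder})")


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: center and scale each spectrum to mean 0, sd 1.

    Uses the population standard deviation (divide by n). Removes per-sample
    multiplicative scatter and additive baseline exactly when the corruption
    is an affine map of a common curve.
    """
    mean = ds.X.mean(axis=1, keepdims=True)
    sd = ds.X.std(axis=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise DegenerateSpectrumError(
            f"constant spectrum at row {int(degenerate[0])}: sd is zero"
        )
    return ds.with_X((ds.X - mean) / sd, note="snv")


def preprocess(ds: SpectralDataset, lo_nm: float | None = None,
               hi_nm: float | None = None, window: int = 3, polyorder: int = 0,
               apply_snv: bool = True) -> SpectralDataset:
    """Standard chain: optional trim, then SG smoothing, then SNV."""
    if lo_nm is not None and hi_nm is not None:
        ds = trim_bands(ds, lo_nm, hi_nm)
    ds = sg_smooth(ds, window=window, polyorder=polyorder)
    if apply_snv:
        ds = snv(ds)
    return ds
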