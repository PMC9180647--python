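"""Sample-by-wavelength spectral tables with residue-level and variety labels.

The on-disk form is a plain CSV with columns ``sample_id, variety, level``
followed by one reflectance column per band, named by its center wavelength
in nm (e.g. ``476.0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VARIETIES = ("Cabernet", "Red", "Munage")


@dataclass
class SpectralDataset:
    """n_samples x n_bands reflectance matrix with labels.

    Attributes
    ----------
    X : float array, shape (n_samples, n_bands)
    wavelengths_nm : float array, strictly increasing band centers
    y : int array, pesticide-residue level per sample (0..3)
    variety : object array of variety names
    provenance : free-text note on instrument / grid / preprocessing history
    """

    X: np.ndarray
    wavelengths_nm: np.ndarray
    y: np.ndarray
    variety: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.variety = np.asarray(self.variety, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != self.wavelengths_nm.size:
            raise ValueError("number of X columns must match wavelength grid")
        if not (len(self.y) == len(self.variety) == self.X.shape[0]):
            raise ValueError("label lengths must match number of samples")
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def with_X(self, X: np.ndarray, note: str = "") -> "SpectralDataset":
        """Copy with a new spectral matrix (same labels); append a provenance note."""
        prov = self.provenance + ("; " + note if note else "")
        return replace(self, X=np.asarray(X, dtype=float), provenance=prov)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{w:g}": self.X[:, i] for i, w in enumerate(self.wavelengths_nm)}
        return pd.DataFrame(
            {"sample_id": np.arange(self.n_samples), "variety": self.variety,
             "level": self.y, **cols}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "SpectralDataset":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c not in ("sample_id", "variety", "level")]
        wl = np.array([float(c) for c in band_cols])
        order = np.argsort(wl)
        return cls(
            X=df[band_cols].to_numpy(dtype=float)[:, order],
            wavelengths_nm=wl[order],
            y=df["level"].to_numpy(dtype=int),
            variety=df["variety"].to_numpy(dtype=object),
            provenance=provenance,
        )

    def subset(self, idx) -> "SpectralDataset":
        idx = np.asarray(idx)
        return SpectralDataset(self.X[idx], self.wavelengths_nm, self.y[idx],
                               self.variety[idx], self.provenance)
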