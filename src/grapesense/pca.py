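"""PCA score exploration with confidence ellipses for class visualization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.decomposition import PCA


@dataclass
class PcaResult:
    """Mean-centered PCA of a sample x band matrix.

    Loadings have orthonormal columns; component signs are fixed so each
    loading's largest-magnitude element is positive, making score plots
    reproducible across runs and libraries.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        r = self.explained_variance_ratio
        if np.any(np.diff(r) > 1e-12) or np.any(r < -1e-12) or r.sum() > 1 + 1e-10:
            raise ValueError("explained-variance ratios must be nonincreasing fractions")


@dataclass
class EllipseParams:
    """A 2-D Gaussian confidence ellipse: center, semi-axes, rotation."""

    center: np.ndarray
    semi_axes: np.ndarray
    rotation_rad: float
    level: float

    def __post_init__(self) -> None:
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership test for n x 2 points (boundary counts as inside)."""
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        rot = np.array([[c, s], [-s, c]])  # rotate by -rotation_rad
        local = (np.asarray(points) - self.center) @ rot.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + (
            local[:, 1] / self.semi_axes[1]
        ) ** 2 <= 1.0


def fit_pca(X: np.ndarray, n_components: int) -> PcaResult:
    """Mean-centered PCA with a deterministic sign convention."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_bands)"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # p x k, orthonormal columns
    # sign convention: largest-magnitude element of each loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return PcaResult(
        scores=scores * flip,
        loadings=loadings * flip,
        explained_variance_ratio=model.explained_variance_ratio_,
        center=model.mean_,
    )


def confidence_ellipse(scores2d: np.ndarray, level: float = 0.95) -> EllipseParams:
    """Confidence ellipse of the fitted 2-D Gaussian at the chi2(2) quantile.

    Semi-axes are sqrt(q * eigenvalues) of the sample covariance, where q is
    the chi-square quantile of ``level`` with 2 degrees of freedom.
    """
    pts = np.asarray(scores2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores2d must be n x 2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 0:
        raise ValueError("degenerate covariance: points are collinear")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = chi2.ppf(level, df=2)
    return EllipseParams(
        center=center,
        semi_axes=np.sqrt(q * eigvals),
        rotation_rad=float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])),
        level=level,
    )
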