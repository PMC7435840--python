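"""Deterministic principal component analysis for exploratory score plots.

The fit is SVD-based with a fixed sign convention (the largest-magnitude
element of each loading is positive), so score plots are reproducible across
runs and platforms.  A per-plane Hotelling T-squared ellipse marks the
confidence region used to flag samples outside the licit cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectraSet


@dataclass
class PcaModel:
    center: np.ndarray
    scale: np.ndarray | None           # None for mean-centering only
    loadings: np.ndarray               # (n_variables, A), orthonormal columns
    eigenvalues: np.ndarray            # score variance per PC, denominator I-1
    explained_fraction: np.ndarray
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectraSet):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


def fit_pca(data, n_components: int, scaling: str = "center") -> PcaModel:
    """Fit PCA on mean-centered (optionally autoscaled) data.

    Parameters
    ----------
    data : SpectraSet or ndarray (n_samples, n_variables)
    n_components : number of PCs, at most min(n_samples - 1, n_variables)
    scaling : "center" (default) or "autoscale"
    """
    X = _as_matrix(data)
    I, J = X.shape
    if I < 2:
        raise ValueError("PCA needs at least two samples")
    max_a = min(I - 1, J)
    if not (1 <= n_components <= max_a):
        raise ValueError(f"n_components must be in [1, {max_a}]")
    center = X.mean(axis=0)
    if scaling == "center":
        scale = None
        Z = X - center
    elif scaling == "autoscale":
        scale = X.std(axis=0, ddof=1)
        if np.any(scale <= 0):
            bad = np.flatnonzero(scale <= 0)
            raise ValueError(f"zero-variance variables under autoscaling: {bad.tolist()}")
        Z = (X - center) / scale
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    _, sv, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:n_components].T.copy()
    # sign convention: largest-magnitude element of each loading positive
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] = -loadings[:, a]
    eig_all = sv**2 / (I - 1)
    total = eig_all.sum()
    eigenvalues = eig_all[:n_components]
    explained = eigenvalues / total if total > 0 else np.zeros(n_components)
    return PcaModel(
        center=center,
        scale=scale,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_fraction=explained,
        n_samples=I,
    )


def project(model: PcaModel, data) -> np.ndarray:
    """Scores of samples in the model's PC space."""
    X = _as_matrix(data)
    if X.shape[1] != model.center.size:
        raise ValueError(
            f"data has {X.shape[1]} variables, model expects {model.center.size}"
        )
    Z = X - model.center
    if model.scale is not None:
        Z = Z / model.scale
    return Z @ model.loadings


def explained_variance_table(model: PcaModel) -> pd.DataFrame:
    frac = model.explained_fraction
    return pd.DataFrame(
        {
            "pc": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "explained_pct": 100 * frac,
            "cumulative_pct": 100 * np.cumsum(frac),
        }
    )


@dataclass
class Ellipse:
    """Hotelling T-squared confidence region in one score plane."""

    center: np.ndarray        # (2,)
    semi_axes: np.ndarray     # (2,) major/minor
    rotation: float           # radians, orientation of the first axis
    covariance: np.ndarray    # (2, 2) score covariance
    limit: float              # Mahalanobis-squared boundary value
    gamma: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        d2 = np.einsum("ij,jk,ik->i", pts, np.linalg.inv(self.covariance), pts)
        return d2 <= self.limit

    def boundary(self, n_points: int = 200) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        rot = np.array(
            [[np.cos(self.rotation), -np.sin(self.rotation)],
             [np.sin(self.rotation), np.cos(self.rotation)]]
        )
        return self.center + (circle * self.semi_axes) @ rot.T


def hotelling_ellipse(scores: np.ndarray, gamma: float = 0.95) -> Ellipse:
    """Hotelling T-squared ellipse at confidence ``gamma`` for a score plane.

    The region is ``(t - mean)' S^-1 (t - mean) <= 2 (I - 1) / (I - 2) *
    F^-1(gamma; 2, I - 2)`` with S the 2x2 empirical score covariance.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be a 2-column matrix")
    I = scores.shape[0]
    if I < 3:
        raise ValueError("need at least 3 samples")
    if not (0 < gamma < 1):
        raise ValueError("gamma must be in (0, 1)")
    center = scores.mean(axis=0)
    S = np.cov(scores.T, ddof=1)
    if np.linalg.matrix_rank(S) < 2:
        raise ValueError("singular score covariance")
    limit = 2.0 * (I - 1) / (I - 2) * stats.f.ppf(gamma, 2, I - 2)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi_axes = np.sqrt(eigval * limit)
    rotation = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return Ellipse(
        center=center,
        semi_axes=semi_axes,
        rotation=rotation,
        covariance=S,
        limit=limit,
        gamma=gamma,
    )
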