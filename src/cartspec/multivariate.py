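"""Spectral data-matrix assembly and correlation-mode PCA.

The multivariate stage stacks 15 randomly chosen ROI pixel spectra per
sample and zone into the d x m matrix X (rows = observations, columns =
wavenumbers; the 10-sample, 3-zone design with the 1730-960 cm^-1 grid
gives 450 x 196) with six (zone, group) class labels.  Columns are
z-scored so the PCA eigendecomposition acts on the correlation matrix;
components are selected by the Kaiser-Guttmann rule (eigenvalue > 1) or
a scree elbow formalized as the maximum second difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ROISet
from .spectra import SpectralCube

MATRIX_REGION = (1730.0, 960.0)


@dataclass
class DataMatrix:
    """Observations x wavenumbers spectral matrix with class labels."""

    X: np.ndarray
    labels: pd.DataFrame  # columns: zone, group, animal_id
    wavenumbers: np.ndarray
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.labels) != X.shape[0]:
            raise ValueError("labels must have one row per observation")
        if self.wavenumbers.size != X.shape[1]:
            raise ValueError("wavenumbers must have one entry per column")
        self.X = X

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def class_labels(self) -> np.ndarray:
        """Six-class labels of the form 'C-SZ' ... 'HMB-DZ'."""
        return (self.labels["group"].astype(str) + "-" + self.labels["zone"].astype(str)).to_numpy()


def assemble_matrix(
    entries: list[tuple[SpectralCube, ROISet]],
    spectra_per_sample: int = 15,
    seed: int = 0,
) -> DataMatrix:
    """Random ROI-pixel spectra from each (sample, zone) cube, stacked.

    ``entries`` pairs each preprocessed cube with its ROI set; from the ROI
    pixel pool of each cube, ``spectra_per_sample`` pixels are drawn without
    replacement (seeded).
    """
    if not entries:
        raise ValueError("no cubes supplied")
    grid = entries[0][0].grid
    rows, labels = [], []
    rng = np.random.default_rng(seed)
    for cube, rois in entries:
        if cube.grid.shape != grid.shape or not np.allclose(cube.grid, grid):
            raise ValueError("all cubes must share one wavenumber grid")
        pool = rois.pixel_indices()
        if len(pool) < spectra_per_sample:
            raise ValueError(
                f"cube {cube.animal_id}/{cube.zone}: only {len(pool)} ROI pixels for "
                f"{spectra_per_sample} requested spectra"
            )
        picks = rng.choice(len(pool), size=spectra_per_sample, replace=False)
        for p in picks:
            iy, ix = pool[p]
            rows.append(cube.data[iy, ix])
            labels.append({"zone": cube.zone, "group": cube.group, "animal_id": cube.animal_id})
    return DataMatrix(
        X=np.vstack(rows),
        labels=pd.DataFrame(labels),
        wavenumbers=grid.copy(),
        standardized=False,
    )


def standardize(dm: DataMatrix, ddof: int = 1) -> DataMatrix:
    """Column z-scores; reports zero-variance columns by index."""
    mu = dm.X.mean(axis=0)
    sd = dm.X.std(axis=0, ddof=ddof)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance columns at indices {dead.tolist()}")
    return DataMatrix(
        X=(dm.X - mu) / sd,
        labels=dm.labels,
        wavenumbers=dm.wavenumbers,
        standardized=True,
        column_means=mu,
        column_sds=sd,
    )


@dataclass
class PCAResult:
    scores: np.ndarray  # d x K
    loadings: np.ndarray  # m x K, orthonormal columns
    eigenvalues: np.ndarray  # all m eigenvalues, non-increasing
    explained_pct: np.ndarray  # % of total variance per component

    def summary(self, k: int = 5) -> pd.DataFrame:
        k = min(k, self.eigenvalues.size)
        return pd.DataFrame(
            {
                "component": np.arange(1, k + 1),
                "eigenvalue": self.eigenvalues[:k],
                "explained_pct": self.explained_pct[:k],
                "cumulative_pct": np.cumsum(self.explained_pct)[:k],
            }
        )


def pca(dm: DataMatrix, n_components: int | None = None) -> PCAResult:
    """Eigendecomposition of the correlation matrix of a standardized matrix."""
    if not dm.standardized:
        raise ValueError("PCA expects a standardized (correlation-mode) matrix")
    if dm.d < 2:
        raise ValueError("need at least 2 observations")
    corr = dm.X.T @ dm.X / (dm.d - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading element of each component positive
    for j in range(eigvecs.shape[1]):
        peak = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[peak, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    explained = 100.0 * eigvals / eigvals.sum()
    K = n_components or dm.m
    return PCAResult(
        scores=dm.X @ eigvecs[:, :K],
        loadings=eigvecs[:, :K],
        eigenvalues=eigvals,
        explained_pct=explained,
    )


def select_components(eigenvalues, method: str = "kaiser") -> int:
    """Kaiser-Guttmann (eigenvalue > 1) or scree-elbow component count.

    The scree elbow is formalized as the interior point with the maximum
    second difference of the sorted eigenvalues; components before the
    elbow are retained.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted in non-increasing order")
    if method == "kaiser":
        return int(np.sum(ev > 1.0))
    if method == "scree":
        if ev.size < 3:
            return 1
        second = ev[:-2] - 2.0 * ev[1:-1] + ev[2:]  # index k corresponds to ev[k+1]
        return int(np.argmax(second) + 1)
    raise ValueError(f"unknown selection method {method!r}")
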