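"""Low-dimensional state-space projection and quasi-potential landscape.

Cells from all time points are projected jointly by PCA so trajectories are
comparable across snapshots; the 2-D cell density over (PC1, PC2), smoothed
with a Gaussian filter, is rendered as a quasi-potential elevation
U = −log(p + 1) relative to a base level of 0, so attractors appear as wells.
The landscape is a visual guide to attractor occupancy, not a dynamical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


@dataclass
class Projection:
    """PCA scores, loadings and variance explained, with the fitting frame."""

    scores: pd.DataFrame          # n cells x K
    loadings: pd.DataFrame        # m genes x K, columns orthonormal
    variance_explained: np.ndarray
    mean: pd.Series               # per-gene centering offsets
    scale: pd.Series | None       # per-gene scaling divisors (None if unscaled)


def pca_project(x: ExpressionMatrix, K: int = 3, scale: bool = False) -> Projection:
    """Principal-component projection of the full concatenated ensemble.

    Fits centered (optionally unit-variance-scaled) PCA on all cells at once —
    never per group — and fixes the sign of each component by making its
    largest-magnitude gene loading positive, so results are deterministic.
    """
    a = x.values.to_numpy(dtype=float)
    n, m = a.shape
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(n, m)={min(n, m)}")
    mean = a.mean(axis=0)
    centered = a - mean
    sd = None
    if scale:
        sd = centered.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot unit-scale a zero-variance gene")
        centered = centered / sd
    rank = np.linalg.matrix_rank(centered)
    if K > rank:
        raise ValueError(f"K={K} exceeds matrix rank {rank}")
    pca = PCA(n_components=K, svd_solver="full")
    scores = pca.fit_transform(centered)
    loadings = pca.components_.T  # m x K
    for k in range(K):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(K)]
    return Projection(
        scores=pd.DataFrame(scores, index=x.cell_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=x.gene_ids, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_.copy(),
        mean=pd.Series(mean, index=x.gene_ids, name="mean"),
        scale=None if sd is None else pd.Series(sd, index=x.gene_ids, name="scale"),
    )


@dataclass
class LandscapeGrid:
    """Smoothed cell-count surface p and its elevation U = −log(p + 1)."""

    grid: np.ndarray       # G x G smoothed counts, >= 0
    elevation: np.ndarray  # G x G, <= 0
    x_edges: np.ndarray
    y_edges: np.ndarray
    sigma: float


def _gaussian_transfer(size: int, sigma: float) -> np.ndarray:
    """1-D Gaussian smoothing matrix with columns renormalized to sum 1.

    Column-stochastic, so smoothing conserves total mass exactly even where
    the kernel is truncated at the grid boundary.
    """
    radius = max(1, int(np.ceil(4.0 * sigma)))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    t = np.zeros((size, size))
    for src in range(size):
        rows = src + offsets
        ok = (rows >= 0) & (rows < size)
        t[rows[ok], src] = kernel[ok]
    return t / t.sum(axis=0, keepdims=True)


def quasipotential(scores, grid_size: int = 50, sigma: float = 2.0) -> LandscapeGrid:
    """Quasi-potential landscape over two state-space coordinates.

    Histograms the cells on a ``grid_size``² lattice spanning the data range
    padded by 10%, smooths the counts with a Gaussian of width ``sigma`` (in
    grid-cell units, boundary-renormalized so mass is conserved), and sets the
    elevation to −log(p + 1): 0 where empty, negative in occupied wells.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an n x 2 array of coordinates")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 cells for a landscape")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if grid_size < 16:
        raise ValueError("grid_size must be >= 16")

    def padded_edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo if hi > lo else 1.0
        return np.linspace(lo - 0.1 * span, hi + 0.1 * span, grid_size + 1)

    x_edges = padded_edges(pts[:, 0])
    y_edges = padded_edges(pts[:, 1])
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    t = _gaussian_transfer(grid_size, sigma)
    p = t @ counts @ t.T
    return LandscapeGrid(grid=p, elevation=-np.log(p + 1.0),
                         x_edges=x_edges, y_edges=y_edges, sigma=float(sigma))


def landscape_table(grid: LandscapeGrid) -> pd.DataFrame:
    """Tidy (x, y, p, U) table of bin centers for export."""
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                         "p": grid.grid.ravel(), "u": grid.elevation.ravel()})


def local_minima(elevation: np.ndarray, depth: float = 0.0) -> list[tuple[int, int]]:
    """Grid cells strictly lower than all 8 neighbours and below ``depth``."""
    g = np.asarray(elevation)
    minima = []
    for i in range(1, g.shape[0] - 1):
        for j in range(1, g.shape[1] - 1):
            window = g[i - 1:i + 2, j - 1:j + 2].copy()
            center = window[1, 1]
            window[1, 1] = np.inf
            if center < window.min() and center < depth:
                minima.append((i, j))
    return minima
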