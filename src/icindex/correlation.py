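"""Ensemble correlation statistics of the cells × genes data matrix.

Two views of the same matrix carry the early-warning signal of a critical
state transition: the n × n Pearson correlations between cell state vectors
(falling as the progenitor attractor flattens and cells diversify) and the
m × m correlations between gene vectors (rising as cells align along the exit
direction).  This module computes both matrices, their off-diagonal averages
⟨R(S^k, S^l)⟩ and ⟨|R(g_i, g_j)|⟩, a per-cell coefficient-of-variation
dispersion measure, and the resampled 1−R dissimilarity between two bulk
expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


class DegenerateEnsembleError(ValueError):
    """Every vector pair was dropped; the correlation average is undefined."""


def _pearson_rows(a: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson correlation between all row pairs of ``a``.

    Rows with zero variance get NaN against every partner (Pearson is
    undefined there); the count of dropped off-diagonal pairs is returned.
    Valid diagonal entries are exactly 1.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    centered = a - a.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    bad = norms == 0.0
    safe = np.where(bad, 1.0, norms)
    r = (centered @ centered.T) / np.outer(safe, safe)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    n_bad = int(bad.sum())
    dropped = n_bad * (n - 1) - n_bad * (n_bad - 1) // 2
    return r, dropped


def _default_genes(x: ExpressionMatrix, genes) -> list[str]:
    # Control (housekeeping) genes are excluded from the ensemble statistics
    # unless a subset is given explicitly.
    return x.target_genes if genes is None else list(genes)


def cell_cell_correlation(x: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """n × n Pearson correlation matrix R(S^k, S^l) between cell vectors."""
    genes = _default_genes(x, genes)
    if len(genes) < 3:
        raise ValueError(f"cell-cell correlation needs >= 3 genes, got {len(genes)}")
    r, _ = _pearson_rows(x.values.loc[:, genes].to_numpy())
    return pd.DataFrame(r, index=x.cell_ids, columns=x.cell_ids)


def gene_gene_correlation(x: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """m × m Pearson correlation matrix R(g_i, g_j) between gene vectors."""
    genes = _default_genes(x, genes)
    if x.n_cells < 3:
        raise ValueError(f"gene-gene correlation needs >= 3 cells, got {x.n_cells}")
    r, _ = _pearson_rows(x.values.loc[:, genes].to_numpy().T)
    return pd.DataFrame(r, index=genes, columns=genes)


def _offdiag_values(r: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(r, k=1)
    vals = r[iu]
    return vals[~np.isnan(vals)]


@dataclass
class CorrelationSummary:
    """The two correlation matrices and their off-diagonal averages.

    ``mean_cell_cell`` is the signed mean ⟨R(S^k, S^l)⟩; ``mean_abs_gene_gene``
    is the mean of absolute values ⟨|R(g_i, g_j)|⟩ — the asymmetry the index
    formula prescribes.  The signed gene–gene mean is kept as a diagnostic.
    """

    cell_cell_matrix: pd.DataFrame
    gene_gene_matrix: pd.DataFrame
    mean_cell_cell: float
    mean_abs_gene_gene: float
    mean_gene_gene_signed: float
    n_cells: int
    n_genes: int
    dropped_pairs: int


def summarize(x: ExpressionMatrix, genes=None) -> CorrelationSummary:
    """Compute both correlation matrices and their averages for one ensemble."""
    genes = _default_genes(x, genes)
    cc = cell_cell_correlation(x, genes)
    gg = gene_gene_correlation(x, genes)
    cc_vals = _offdiag_values(cc.to_numpy())
    gg_vals = _offdiag_values(gg.to_numpy())
    if cc_vals.size < 2 or gg_vals.size < 2:
        raise DegenerateEnsembleError(
            "degenerate ensemble: fewer than 2 valid pairs on one side")
    n_cell_pairs = x.n_cells * (x.n_cells - 1) // 2
    n_gene_pairs = len(genes) * (len(genes) - 1) // 2
    dropped = (n_cell_pairs - cc_vals.size) + (n_gene_pairs - gg_vals.size)
    return CorrelationSummary(
        cell_cell_matrix=cc,
        gene_gene_matrix=gg,
        mean_cell_cell=float(cc_vals.mean()),
        mean_abs_gene_gene=float(np.abs(gg_vals).mean()),
        mean_gene_gene_signed=float(gg_vals.mean()),
        n_cells=x.n_cells,
        n_genes=len(genes),
        dropped_pairs=int(dropped),
    )


def per_cell_cv(x: ExpressionMatrix) -> tuple[pd.Series, float]:
    """Per-cell coefficient of variation of expression across genes.

    Log-scale expression can be negative, so when the global minimum falls
    below +1 the whole matrix is first shifted by a constant that puts it at
    +1 (the shift is returned — the CV is a dispersion descriptor in that
    recorded frame, not a physical quantity).  Already-positive matrices are
    left untouched, preserving the scale invariance of sd/mean.  Population
    standard deviation (divide by m) over mean.
    """
    shift = max(0.0, 1.0 - float(x.values.to_numpy().min()))
    shifted = x.values.to_numpy() + shift
    means = shifted.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("cell mean <= 0 after positivity shift")
    cv = shifted.std(axis=1, ddof=0) / means
    return pd.Series(cv, index=x.cell_ids, name="cv"), shift


def _pearson_pair(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def profile_dissimilarity(a, b, gene_fraction: float = 0.3,
                          n_resamples: int = 10_000, seed: int | None = None,
                          max_redraws: int = 100) -> tuple[float, float]:
    """Transcriptome dissimilarity 1 − R between two expression profiles.

    The point estimate uses all genes.  The uncertainty is the standard
    deviation of 1 − R over ``n_resamples`` random subsets of
    ``ceil(gene_fraction · m)`` genes, the same subset applied to both
    profiles per resample.  Zero-variance subsets are redrawn (capped).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 10:
        raise ValueError("profiles must be equal-length 1-D vectors of >= 10 genes")
    if not 0 < gene_fraction <= 1:
        raise ValueError("gene_fraction must be in (0, 1]")
    point = 1.0 - _pearson_pair(a, b)
    if n_resamples < 1:
        return point, 0.0
    m = a.size
    size = int(np.ceil(gene_fraction * m))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_resamples)
    for i in range(n_resamples):
        for attempt in range(max_redraws + 1):
            idx = rng.choice(m, size=size, replace=False)
            r = _pearson_pair(a[idx], b[idx])
            if not np.isnan(r):
                break
        else:
            raise RuntimeError("zero-variance subsets persisted past redraw cap")
        draws[i] = 1.0 - r
    return point, float(draws.std(ddof=0))
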