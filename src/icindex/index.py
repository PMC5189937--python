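"""The critical state transition index I_C and its inference.

I_C(t) = ⟨|R(g_i, g_j)|⟩ / ⟨R(S^k, S^l)⟩ — the mean absolute gene–gene
Pearson correlation over the mean cell–cell correlation of a cells × genes
snapshot.  Around a stable attractor the two averages are of comparable size
and I_C ≈ 1; as the ensemble approaches a tipping point cells diversify
(denominator falls) while genes co-vary along the exit direction (numerator
rises), so I_C increases toward a maximum near the transition.

Inference is resampling-based: the SEM comes from bootstrapping cells, the
significance of a deviation from 1 from a per-gene permutation null, and
robustness from random gene subsampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationSummary, _offdiag_values, _pearson_rows, summarize
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


class NonPositiveDenominatorError(ValueError):
    """⟨R(S^k, S^l)⟩ ≤ 0: the cell ensemble has no common orientation."""


MIN_GROUP_CELLS = 10


@dataclass
class ICResult:
    """I_C for one cell group, with bootstrap uncertainty and components."""

    ic: float
    sem: float
    group: str
    n_cells: int
    n_genes: int
    components: CorrelationSummary


@dataclass
class NullDistribution:
    """Observed statistic, permutation null values and +1-corrected p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    scheme: str
    seed: int


def _ic_from_matrix(a: np.ndarray) -> tuple[float, float, float]:
    """(ic, mean_cell_cell, mean_abs_gene_gene) of a raw cells × genes array."""
    cc, _ = _pearson_rows(a)
    gg, _ = _pearson_rows(a.T)
    cc_vals = _offdiag_values(cc)
    gg_vals = _offdiag_values(gg)
    if cc_vals.size == 0 or gg_vals.size == 0:
        return math.nan, math.nan, math.nan
    mean_cc = float(cc_vals.mean())
    mean_gg = float(np.abs(gg_vals).mean())
    ic = mean_gg / mean_cc if mean_cc > 0 else math.nan
    return ic, mean_cc, mean_gg


def compute_ic(x: ExpressionMatrix, cells=None, genes=None, *,
               group: str = "all", b_sem: int = 200,
               seed: int | None = None,
               min_cells: int = MIN_GROUP_CELLS) -> ICResult:
    """Compute I_C for one cell group with a cell-bootstrap SEM.

    ``cells``/``genes`` select the group and gene subset (default: all cells,
    target genes only).  The SEM is the standard deviation of I_C over
    ``b_sem`` resamples of cells with replacement — cells are the sampling
    unit of the ensemble.  ``min_cells`` guards against ensembles too small
    to call a statistical ensemble; lower it only for algebraic checks.
    """
    sub = x.subset(cells=cells)
    if sub.n_cells < min_cells:
        raise ValueError(f"group '{group}' has {sub.n_cells} cells; "
                         f"need >= {min_cells}")
    comp = summarize(sub, genes=genes)
    if comp.mean_cell_cell <= 0:
        raise NonPositiveDenominatorError(
            "denominator non-positive: cell ensemble has no common orientation")
    ic = comp.mean_abs_gene_gene / comp.mean_cell_cell

    sem = 0.0
    if b_sem > 0:
        gene_list = sub.target_genes if genes is None else list(genes)
        a = sub.values.loc[:, gene_list].to_numpy()
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(b_sem):
            idx = rng.integers(0, a.shape[0], size=a.shape[0])
            rep_ic, _, _ = _ic_from_matrix(a[idx])
            if np.isfinite(rep_ic):
                reps.append(rep_ic)
        if len(reps) >= 2:
            sem = float(np.std(reps, ddof=1))
    return ICResult(ic=float(ic), sem=sem, group=group, n_cells=sub.n_cells,
                    n_genes=comp.n_genes, components=comp)


def ic_timecourse(x: ExpressionMatrix, group_by=("time_point",), genes=None, *,
                  b_sem: int = 200, seed: int | None = None) -> list[ICResult]:
    """I_C per metadata group, ordered by time of first appearance.

    Groups failing the size or denominator preconditions are skipped with a
    logged reason.  The same gene subset is used throughout so indices are
    comparable across time.
    """
    group_by = list(group_by)
    meta = x.cell_meta
    keys = meta[group_by].astype(str).agg("/".join, axis=1)
    results: list[ICResult] = []
    for label in keys.unique():  # order of appearance == time order of the design
        cells = list(keys.index[keys == label])
        try:
            results.append(compute_ic(x, cells=cells, genes=genes, group=label,
                                      b_sem=b_sem, seed=seed))
        except (ValueError, NonPositiveDenominatorError) as exc:
            logger.warning("skipping group '%s': %s", label, exc)
    return results


def permutation_null(x: ExpressionMatrix, cells=None, genes=None, *,
                     B: int = 999, seed: int = 0, statistic: str = "log_ic",
                     max_redraws: int = 100) -> NullDistribution:
    """Permutation significance of I_C against gene-randomized data.

    Each null replicate permutes every gene's values independently across the
    group's cells, destroying gene–gene and structured cell–cell correlation
    while preserving each gene's marginal distribution.  The default
    statistic is log I_C, right-tailed: large values mean the gene–gene
    correlation is high relative to the cell–cell correlation — the
    transition signature no gene-wise randomization can reproduce.
    ``statistic="abs_log_ic"`` gives the two-sided deviation-from-1 variant.
    The p-value carries the +1 finite-sample correction
    p = (1 + #{null ≥ observed}) / (1 + B).
    """
    if B < 99:
        raise ValueError(f"B must be >= 99, got {B}")
    if statistic not in ("log_ic", "abs_log_ic"):
        raise ValueError(f"unknown statistic: {statistic}")
    stat = abs if statistic == "abs_log_ic" else (lambda v: v)
    sub = x.subset(cells=cells)
    gene_list = sub.target_genes if genes is None else list(genes)
    a = sub.values.loc[:, gene_list].to_numpy()
    ic, mean_cc, _ = _ic_from_matrix(a)
    if not np.isfinite(ic) or mean_cc <= 0:
        raise NonPositiveDenominatorError(
            "denominator non-positive: cell ensemble has no common orientation")
    observed = stat(math.log(ic))

    rng = np.random.default_rng(seed)
    null_values = np.empty(B)
    for b in range(B):
        for attempt in range(max_redraws + 1):
            perm = a.copy()
            for j in range(perm.shape[1]):
                perm[:, j] = perm[rng.permutation(perm.shape[0]), j]
            rep_ic, rep_cc, _ = _ic_from_matrix(perm)
            if np.isfinite(rep_ic) and rep_cc > 0:
                break
        else:
            raise RuntimeError("permutation redraw cap exhausted "
                               "(denominator non-positive in every redraw)")
        null_values[b] = stat(math.log(rep_ic))
    p = (1 + int((null_values >= observed).sum())) / (1 + B)
    return NullDistribution(observed=observed, null_values=null_values,
                            p_value=p, scheme=f"per-gene permutation/{statistic}",
                            seed=seed)


def gene_subsample_robustness(x: ExpressionMatrix, sizes, n_draws: int,
                              seed: int = 0, cells=None) -> pd.DataFrame:
    """I_C over random gene subsets of the given sizes.

    Returns a tidy table (size, draw, ic, mean_cell_cell, mean_abs_gene_gene);
    one row per draw.  Sizes below 3 are skipped with a warning; sizes above
    the number of available genes are an error.  Reproducible from ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    sub = x.subset(cells=cells)
    gene_list = sub.target_genes
    m = len(gene_list)
    for size in sizes:
        if size > m:
            raise ValueError(f"subset size {size} exceeds available genes ({m})")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size < 3:
            logger.warning("skipping gene subset size %d (< 3)", size)
            continue
        for draw in range(n_draws):
            chosen = [gene_list[i] for i in rng.choice(m, size=size, replace=False)]
            ic, mean_cc, mean_gg = _ic_from_matrix(
                sub.values.loc[:, chosen].to_numpy())
            rows.append({"size": size, "draw": draw, "ic": ic,
                         "mean_cell_cell": mean_cc, "mean_abs_gene_gene": mean_gg})
    return pd.DataFrame(rows)


def robustness_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean and sd of I_C from a robustness table."""
    return (table.groupby("size")["ic"].agg(["mean", "std", "count"])
            .rename(columns={"std": "sd", "count": "n_draws"}).reset_index())
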