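# icindex

Early-warning analysis of **critical state transitions** in single-cell
expression ensembles.

When a multipotent progenitor population is driven toward a fate decision, the
attractor that stabilizes its gene-expression state flattens and finally
vanishes — a bifurcation.  Even without knowing the regulatory network or its
bifurcation parameter, the approach to that tipping point leaves statistical
fingerprints in snapshots of *n* cells × *m* genes: cells diversify (cell–cell
correlation falls) while genes start to co-vary along the exit direction
(gene–gene correlation rises).  `icindex` computes the index that combines
both signals,

```
I_C(t) = ⟨|R(g_i, g_j)|⟩ / ⟨R(S^k, S^l)⟩
```

the mean absolute Pearson correlation over all gene-vector pairs divided by
the mean Pearson correlation over all cell-state-vector pairs of the data
matrix **X**(t).  A rise of I_C toward a maximum across sampling times is an
early-warning signal that the population is approaching a critical
transition.

The package is aimed at analysts of single-cell qPCR / RNA-seq time courses
and at modelers who want a controlled testbed.  It provides:

- **`icindex.io`** — single-cell qPCR preprocessing: per-assay
  limit-of-detection (LOD) cutoffs, triplicate medians, ΔCq normalization
  against housekeeping genes, detection-floor imputation, and a delimited-text
  `ExpressionMatrix` format with cell metadata and gene roles.
- **`icindex.correlation`** — cell–cell and gene–gene correlation matrices
  and averages, per-cell CV dispersion, and the resampled 1−R dissimilarity
  between bulk profiles.
- **`icindex.index`** — I_C per group/time point with cell-bootstrap SEM,
  a per-gene permutation null for significance, and gene-subsampling
  robustness.
- **`icindex.state_space`** — joint PCA projection and the quasi-potential
  landscape U = −log(p+1) over smoothed cell density (attractors as wells).
- **`icindex.simulate`** — a stochastic two-master GRN (mutual inhibition +
  self-activation, Hill kinetics) driven slowly through a pitchfork-like
  bifurcation with an instructive bias: synthetic ensembles exhibiting the
  full phenomenology — rising I_C, critical slowing down, and "rebellious"
  cells that commit to the disfavored lineage.
- **`icindex.cli`** — `icindex preprocess | ic | simulate | landscape`
  subcommands for reproducible, config-driven runs.

## Worked example

Simulate the pinned default scenario (500 cells × 12 genes, four sampling
times straddling the tipping point) and compute the I_C timecourse:

```python
from icindex import default_scenario, ic_timecourse

ens = default_scenario(seed=1)
for r in ic_timecourse(ens.to_expression_matrix(), b_sem=0):
    c = r.components
    print(f"{r.group}: <R(cell,cell)>={c.mean_cell_cell:.3f} "
          f"<|R(gene,gene)|>={c.mean_abs_gene_gene:.3f}  I_C={r.ic:.3f}")
```

prints

```
t0: <R(cell,cell)>=0.979 <|R(gene,gene)|>=0.523  I_C=0.534
t1: <R(cell,cell)>=0.973 <|R(gene,gene)|>=0.660  I_C=0.678
t2: <R(cell,cell)>=0.892 <|R(gene,gene)|>=0.976  I_C=1.095
t3: <R(cell,cell)>=0.967 <|R(gene,gene)|>=0.912  I_C=0.943
```

Reading: from t0 to t2 (the snapshot nearest the tipping point) cells
diversify — the cell–cell average falls from 0.98 to 0.89 — while the
gene–gene average nearly doubles, so I_C roughly doubles and peaks at t2.
After the transition (t3) most cells have re-homogenized inside the intended
lineage attractor and I_C falls back; a ~1–3% rebellious minority sits in the
opposite attractor (`ens.snapshots[-1].labels`).

The same analysis from the shell:

```sh
icindex simulate --seed 1 -o run/
icindex ic -i run/ensemble.csv -B 199 --seed 0 -o run/
icindex landscape -i run/ensemble.csv -o run/
```

`run/ic_timecourse.csv` then holds one row per time point (group, n_cells,
n_genes, the two correlation averages, ic, sem, p_value).

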