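# Methods

## The index and what it measures

For a snapshot of *n* cells × *m* genes (log2-scale expression matrix
**X**(t)), let R(S^k, S^l) be the Pearson correlation between the state
vectors of cells k and l (rows) and R(g_i, g_j) the Pearson correlation
between gene vectors i and j (columns).  The critical-transition index is

    I_C(t) = ⟨|R(g_i, g_j)|⟩ / ⟨R(S^k, S^l)⟩ ,

both averages taken over off-diagonal, defined pairs.  The numerator uses
absolute values (correlated and anti-correlated gene pairs both signal
coordination along an exit direction); the denominator is signed — a cell
ensemble with no common orientation (⟨R⟩ ≤ 0) has no meaningful index and
the package raises an error rather than reporting one.  Pairs involving a
zero-variance vector are undefined under Pearson; they are dropped from the
averages and counted (`dropped_pairs`), never substituted by 0, which would
bias the means.

Around a stable attractor, expression fluctuations are roughly isotropic:
cell vectors stay similar (denominator high) and gene pairs are weakly
correlated (numerator low).  Approaching a bifurcation, the restoring force
along the soft direction weakens: cells spread (denominator falls) and genes
co-vary through their loadings on that direction (numerator rises), so I_C
rises toward a maximum near the tipping point.  The post-transition decrease
is an empirical regularity, not a theoretical necessity (ensembles split
across attractors are not ergodic samples of one basin), so the tests assert
the rise and the location of the peak, not the fall.

Note that averages are over *distinct* pairs.  Under this convention,
appending an exact copy of the ensemble leaves the gene–gene average exactly
invariant but adds n unit self-copy pairs to the cell–cell average
(mean′ = (4·Σr + n)/(n(2n−1))); the test suite asserts this exact
relationship rather than a loose "duplication invariance".

## Inference

**SEM.**  Cells are the sampling unit of the ensemble, so the uncertainty of
I_C is the standard deviation over B_sem = 200 bootstrap resamples of cells
with replacement (seeded).

**Permutation null.**  Significance of an elevated I_C is assessed against
ensembles with each gene's values independently permuted across cells.  This
preserves every gene's marginal distribution and the cells' shared mean
profile, while destroying gene–gene and structured cell–cell correlation.
The default statistic is log I_C, right-tailed: gene-wise randomization
collapses the numerator but leaves the profile-driven denominator high, so
null I_C sits well below the observed value whenever transition-like
structure is present.  p = (1 + #{null ≥ observed})/(1 + B) with B ≥ 99; the
+1 correction makes p-values valid and slightly conservative
(super-uniform).  A two-sided variant (|log I_C|) is available via
`statistic="abs_log_ic"`.  The calibration test draws data from the null
scheme itself and checks that the fraction of p ≤ 0.05 stays within exact
binomial 99% bounds.

**Gene-subsampling robustness.**  I_C is recomputed over random gene subsets
of given sizes (without replacement, seeded); the per-size standard
deviation quantifies how the stability of the index grows with the number of
genes.  Since only the *change* of I_C across time carries meaning — its
absolute value depends on the gene set — this is reported as spread, not
bias.

## qPCR preprocessing

Raw data are quantification cycles Cq per (cell, gene, technical replicate),
lower = more transcript.  Steps, in order:

1. **LOD filter per replicate**: replicates at or beyond the gene's
   limit-of-detection cutoff Cq are non-detects.
2. **Median collapse**: one Cq per (cell, gene), the median of passing
   replicates; no passing replicate → non-detect.  Idempotent.
3. **ΔCq**: per cell, reference = mean Cq of its *detected* control
   (housekeeping) genes; expression = reference − Cq, so one PCR cycle ≈ one
   log2 unit.  Cells with no detected control gene, and cells detecting no
   target gene at all, are dropped (logged with counts).
4. **Floor imputation**: non-detects are set to reference − (LOD +
   floor_margin), i.e. `floor_margin` cycles (default 1) below the least
   detectable level, and flagged in a boolean detect mask.  Imputing (rather
   than dropping) keeps the correlation matrices complete so every pair of
   cells/genes is computed on the same set; the mask preserves the
   information for sensitivity analyses.

Control genes are identified by an explicit role column, never by name.
Files are comma- or tab-delimited (auto-detected from the header line),
headers case-insensitive.

**Per-cell CV.**  The coefficient of variation (population sd / mean of a
cell's expression across genes) is a dispersion descriptor with no physical
units on log-scale data; matrices whose global minimum falls below +1 are
shifted so the minimum is +1 first (shift recorded and returned).
Already-positive matrices are left untouched, preserving the scale
invariance of sd/mean.

**Profile dissimilarity.**  1 − R between two bulk profiles on all genes;
the uncertainty is the sd of 1 − R over seeded resamples (default 10,000) of
a 30% gene subset, the same subset applied to both profiles per resample.

## State space

PCA is fitted once on all cells from all time points concatenated (centered;
unit-variance scaling optional and off by default — ΔCq units are already
comparable cycles across genes).  Signs are fixed by making each component's
largest-magnitude loading positive, so projections are deterministic.

The quasi-potential landscape bins the (PC1, PC2) cell coordinates on a
50×50 grid spanning the data range padded by 10%, smooths the counts with a
Gaussian of width σ = 2 grid cells, and reports the elevation
U = −log(p + 1) (0 where empty, wells where cells accumulate).  p is a
smoothed *count* surface, not a normalized density: with a density summing
to 1, −log(p+1) would be vanishingly shallow, whereas counts render visible
wells with a natural base level of 0.  Smoothing uses a separable transfer
matrix whose columns are renormalized where the kernel is truncated at the
grid boundary, so the total smoothed mass equals the cell count exactly
(tested to 1e−8).  The landscape is a visual guide to occupancy; it makes no
claim about the dynamics or its distortion during the bifurcation.

## The bifurcation simulator

**Model.**  The canonical two-master circuit of binary fate choice — two
self-activating, mutually inhibiting regulators x and y with Hill kinetics —
plus linear noisy readout genes:

    dx = [ μ·a·x^h/(S^h + x^h) + b·S^h/(S^h + y^h) + bias − k·x ] dt + σ dW
    dy = [ μ·a·y^h/(S^h + y^h) + b·S^h/(S^h + x^h)        − k·y ] dt + σ dW
    dz_j = decay_j·(basal_j + w_xj·x + w_yj·y − z_j) dt + σ dW

Defaults a = b = k = 1, S = 0.5, h = 4, σ = 0.05.  The bifurcation parameter
μ scales the self-activation/decay balance.  At μ = 1 the symmetric
progenitor state (x = y) is stable; lowering μ destabilizes it.  With
bias = 0 the loss of stability is a pitchfork (the symmetric state's
antisymmetric eigenvalue crosses zero at μ ≈ 0.774 for these parameters);
with the small production bias on x the pitchfork is imperfect and the
progenitor branch instead folds at μ ≈ 0.81, with the x-branch ("intended"
lineage) continuously accessible and the y-branch ("rebellious") reachable
only by noise.  This matches the two scenarios discussed for binary lineage
decisions — symmetric versus imperfect pitchfork — with `bias` as the dial
between them.

**Integration.**  Euler–Maruyama, dt = 0.01, reflecting boundary at 0
(concentrations are non-negative).  Each cell has its own counter-based
noise stream derived from (seed, cell index), so ensembles are bit-exactly
reproducible and per-cell trajectories do not depend on how many cells are
simulated.  Non-finite states raise immediately, naming dt as the suspect.

**Snapshots.**  μ is ramped piecewise-constant: each schedule entry holds μ
for t_segment = 15 time units and a snapshot is taken at the end.
Expression is reported as log2(1 + 20·concentration) — the factor 20 maps
concentrations of order 1 to a few log2 units, mirroring the dynamic range
of ΔCq data.

**Attractor labels.**  Stable fixed points of the master subsystem are found
by multi-start root finding (49 grid starts, deduplicated; stability from
the 2×2 Jacobian).  A cell is assigned to the nearest stable fixed point in
the (x, y) plane if within a capture radius of 25% of the smallest
inter-attractor distance, else `undecided`.  A near-symmetric attractor is
the `progenitor`; post-bifurcation, the branch favored by the sign of the
bias is `intended` and the other `rebellious` (bias = 0 defaults the
x-branch to `intended` — an arbitrary but fixed convention).

**Critical slowing down.**  `relaxation_time` displaces an ensemble from the
progenitor fixed point by a given m-vector and measures the time for the
median displacement to fall below threshold × initial (non-convergence is
reported as right-censored, not raised).  The noise-free measurement is
validated against the linearization prediction log(1/threshold)/|Re λ_max|
from a finite-difference Jacobian at the fixed point; with the perturbation
along the slowest eigenvector and threshold 0.1 the two agree within a few
percent, and both grow monotonically as μ approaches the bifurcation.

**The pinned default scenario** (`data/default_scenario.yaml`): 500 cells,
12 genes (2 masters + 5 x-leaning + 5 y-leaning readouts with varied basal
levels, giving the shared expression profile that real cell ensembles have),
bias 0.04, four sampling times at μ = 1.00, 0.90, 0.82, 0.60 — two
pre-transition samplings, one just above the fold at μ ≈ 0.81, one past it.
All scenario numbers live in this one config file; nothing is hard-coded in
the operations.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* behind the observed statistics: an
ensemble in a flattening attractor yields falling cell–cell correlation,
rising absolute gene–gene correlation, a peaking I_C, growing fluctuation
variance, slowing relaxation, and a bias-controlled rebellious minority.
It deliberately omits cell–cell communication, cell division and death,
transcriptional bursting, dropout beyond the LOD mechanism, and any
gene-regulatory detail beyond the two-master motif.  Passing tests therefore
demonstrate that the statistics behave as the theory predicts on ensembles
with these properties — not that any particular biological dataset will show
them, nor that the 17-gene panels of real experiments are well modeled by 12
linear readouts.  The synthetic qPCR dataset used in the end-to-end pipeline
test re-encodes simulated expression as triplicate Cq values around a
housekeeping reference with 0.05-cycle technical jitter; it is labelled
synthetic throughout.  One instructive artifact: the technical jitter
selectively dilutes the small within-attractor gene–gene correlations and
barely affects the large transition-time ones, so the measured I_C fold
change through the Cq pipeline is *larger* than on the noise-free matrix —
the same behavior expected of real qPCR technical noise.

## Problem sizes and numerical conventions

Property tests run the scenario at its native size (500 cells); seed-sweep
assertions use 20 seeds with ≥ 19/20 (or ≥ 18/20 where the spec of the check
is 90%) required, making them robust to single-seed flukes while keeping the
suite to a couple of minutes.  The bias-response check uses 1,000 cells with
a two-segment schedule (μ = 1.0 → 0.6, t_segment = 10), long enough for
commitment at μ = 0.6 where the symmetric state's unstable eigenvalue is
≈ 0.6.  Correlation matrices are computed by centered dot products with
zero-variance guards and clipped to [−1, 1]; exactness is asserted to 1e−12
against a moment-sum oracle.  The permutation and bootstrap loops redraw
degenerate replicates (non-positive denominator) up to a cap of 100 and
raise if exhausted.  All stochastic entry points take explicit integer
seeds; derived streams use `numpy.random.SeedSequence` spawning.

## Known limitations

- The ΔCq reference convention (mean Cq of detected controls) is a standard
  choice; laboratories using a different reference scheme will get shifted
  absolute expression values (correlations, and hence I_C, are unaffected by
  per-cell shifts).
- I_C is undefined for ensembles whose mean cell–cell correlation is ≤ 0
  (very heterogeneous populations); the package refuses rather than reports.
- The permutation null preserves gene marginals but not any cell-level
  covariate structure; group comparisons should permute within groups.
- The quasi-potential is occupancy-based and time-pooled; it is not a
  potential of the underlying dynamics.
- The simulator's downstream genes are linear readouts; real target genes
  saturate and interact.
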