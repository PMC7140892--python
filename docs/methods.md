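# Methods

`hkgrank` implements a multi-study procedure for identifying stably expressed
reference (housekeeping) genes from heterogeneous expression compendia, and a
synthetic data generator that embeds a known stability structure so the whole
procedure can be validated end to end as a parameter-recovery problem.

## The procedure

Given a collection of independent studies measured on an Affymetrix-style
platform (probe-level perfect-match/mismatch intensities), the pipeline runs:

1. **Study filtration.** Keep studies with more than three samples, no
   duplicated samples, and raw data available.
2. **Normalization tracks.** Each study is normalized independently under
   M parallel tracks (default four: RMA-, MAS5-, Li–Wong- and VSN-style).
   Tracks that natively produce linear intensities (MAS5, Li–Wong) are
   log2-transformed before leaving the module, because the downstream
   stability criteria are stated on log2 expression; each matrix carries a
   `scale_note` flag recording this.
3. **Probe-to-gene collapse.** Probesets annotated to more than one gene are
   deleted; rows with missing values are dropped; a gene covered by several
   probesets gets the per-sample median (the median of an even number of
   values is the mean of the central two).
4. **First-round ranking.** Per study and track, genes are (a) required to be
   detected in every sample (expression at or above a detection floor,
   default the 1st percentile of the study's matrix — a stand-in for
   platform present/absent calls, which plain intensity data do not carry);
   (b) excluded if any single sample deviates from the gene's mean by
   two-fold or more (strict `|x_ij − mean_i| ≥ 1.0` log2 units); and
   (c) sorted by ascending population standard deviation
   `σ = sqrt((1/n) Σ (x_i − x̄)²)` with lexicographic tie-break, truncated to
   the top N.
5. **Second-round aggregation.** Per track, the per-study lists (truncated to
   the target length K) are aggregated into a single list by minimizing the
   mean Spearman footrule distance — over the union of items, rank = position
   if present else K+1, distance = Σ|rank difference| — using a Cross-Entropy
   Monte Carlo optimizer (below).
6. **Consensus.** The M per-track lists are intersected; a gene appearing in
   at least `threshold` of them is a candidate (3 when M = 6; the pipeline
   default is threshold 3 with M = 4, i.e. a strict majority; a single-track
   run degenerates to "candidates = that track's list").
7. **Evaluation.** Two independent stability indexes are computed per gene on
   validation data: the Gini coefficient
   `GC = 2 Σ i·x_(i) / (n Σ x_i) − (n+1)/n` over ascending-sorted
   non-negative values (the ascending sort is required for the weighting to
   be the Gini coefficient and is applied explicitly), and the population SD.
   RNA-seq-style counts are normalized as log2(CPM+1); linear microarray
   matrices as log2 followed by quantile normalization.  Comparison reports
   compute GC on linear-scale values (2^x) and SD on log2 values — GC on
   log-scale values is distorted near zero — and both conventions are
   labeled in the output.

## Cross-Entropy Monte Carlo aggregation

The optimizer maintains a K × |universe| position-probability matrix,
initialized uniformly or biased 3:1 toward the Borda (mean-rank) solution's
positions (the default; it speeds convergence without constraining the
optimum — the best list ever sampled is returned, and the Borda list and the
input lists themselves seed the incumbent).  Each iteration samples
`n_samples = min(10·K·|universe|, 5000)` duplicate-free lists
position-by-position with renormalization, scores them by mean footrule
distance, takes the ρ = 0.1 elite fraction and updates probabilities as
`p ← ν·elite_frequency + (1−ν)·p` with ν = 0.7.  The search stops when the
incumbent objective has not improved for 15 iterations (converged) or after
500 iterations (returned with `converged=false`).  At compendium scale the
candidate universe is first gated to genes appearing in at least half the
input lists; the gate only engages above 100 union items, so desk-scale
problems and the test oracles see the full union.  On small instances
(hundreds of enumerable lists) the optimizer attains the exhaustive optimum
in ≥ 95% of seeded runs, which the test suite checks against an independent
enumeration.

Whether one should aggregate full first-round lists or top-K truncations is
genuinely open; the pipeline feeds top-K truncations (the usual convention
for rank-aggregation tools, and what keeps the universe commensurate with
the output length).  Full-list aggregation remains available by calling the
aggregator directly.

## Normalization track details

* **RMA-style.** Background is removed by subtracting each array's 5th
  percentile (floored at 1) — a deliberate simplification of the usual
  normal+exponential convolution fit, sufficient here because downstream
  analysis consumes only variance ranking, which a location shift does not
  disturb.  Then log2, quantile normalization (ties receive the mean of the
  tied target quantiles), and per-probeset Tukey median polish; the
  summarized expression is overall + sample effects.
* **MAS5-style.** Ideal mismatch IM = MM where MM < PM; otherwise
  IM = PM / 2^SB with SB the probeset's Tukey biweight (c = 5, ε = 1e-4) of
  log2(PM/MM), floored at a contrast of 0.03.  Signal = biweight of
  log2(max(PM − IM, 2⁻²⁰)); each array is then scaled so its 2%-trimmed mean
  of linear signals equals the target (default 500).
* **Li–Wong-style.** No background correction.  Each array is normalized to
  the pseudo-median reference (per-probe median across arrays) by a monotone
  running-median curve fitted over the invariant probe set — probes whose
  rank-difference proportion is below `0.003 + 0.007·(rank/n)`; if none
  qualify, all probes are used with a logged warning.  Per probeset, the
  multiplicative model `PM_ij ≈ θ_j φ_i` is fitted by alternating least
  squares under `‖φ‖² = P` (tol 1e-10, ≤ 200 iterations); expression is
  log2 θ.  Note the normalization step intentionally maps proportional
  arrays onto the reference, so exact rank-1 recovery is a property of the
  ALS fit, not of the end-to-end track.
* **VSN-style.** Each array gets an affine calibration (α_s, β_s), estimated
  by iterated trimmed least squares (trim fraction 0.1) matching the array's
  sorted quantiles to the pseudo-median reference array's, followed by a
  shared generalized-log transform `h(x) = arcsinh((α_s + β_s x − x₀)/λ)/ln 2`.
  The glog scale λ is set to the ratio of the data's additive noise (median
  across-array SD of the lowest-quartile probes) to its multiplicative noise
  (median across-array SD of log intensity in the top quartile), which is
  what equalizes replicate variance across the intensity range; x₀ is the 5th
  percentile of the calibrated intensities.  Degenerate inputs (identical
  arrays, zero noise) fall back to a fixed positive scale, where any λ gives
  the same identical columns.  A non-positive β aborts with a calibration
  error.  Values are already on a log2-like variance-stabilized scale and
  are not logged again.

Two further classic tracks (sequence-aware background correction in the
GCRMA family and the PLIER error model) are not implemented — the first
needs probe sequences, which the data model deliberately omits, and the
second's error model is not publicly specified at implementable detail.  The
registry accepts plugin tracks with the same contract, and the pipeline is
written for any M ≥ 2 (or degenerate M = 1).

## The synthetic generator

Defaults describe the study conditions used throughout the analysis and the
tests: 30 studies of 2,000 genes, 4–24 samples per study in a two-group
condition design, 2% housekeeping genes, 30% condition-responsive genes,
the remainder noisy.  Per-gene log2 baselines are uniform on [5, 12]
(housekeeping on [8, 12]: real reference genes are highly expressed).
Biological noise SD is uniform per archetype — housekeeping 0.05–0.15,
responsive 0.25–0.6, noisy 0.5–1.2 log2 units — and is drawn per
(gene, sample), shared by all probes of the gene.  Responsive genes receive
a condition effect of |Δ| uniform on [1, 3] log2 units with random sign in
each study independently with probability 0.3 (and at least one affected
study each, enforced).

The probe layer adds per-probe affinities (N(0, 0.5) log2, fixed across
arrays and studies, as chip probes are), per-cell measurement noise
(N(0, 0.25) log2 — an ordinary figure for array replicates), an additive
per-array optical background uniform on [20, 60] linear units with per-cell
SD 5, and a mismatch channel MM = 0.6·PM_signal^0.9 + background.  The
separation of shared biological noise from probe-level measurement noise is
what makes the four tracks agree about biology while disagreeing about
near-ties — the behavior that real multi-algorithm comparisons show, and the
reason cross-track consensus filters anything at all.

A companion count generator emits RNA-seq-style matrices from the same
truth: gamma-Poisson (negative binomial) counts with mean proportional to
2^(base + fresh condition effects + noise) times the library size,
dispersion 0.05 by default; dispersion 0 returns the rounded expected means
as the degenerate limit.

What the generator does **not** emulate: probe GC content and
sequence-specific cross-hybridization, batch or lab effects correlated
across studies, tissue- or single-cell-level structure, dropout, and any
real platform's annotation arithmetic.  Passing the recovery tests therefore
shows that the pipeline's machinery is correct and well-calibrated under the
assumed noise model — not that it would reproduce any particular real-data
candidate list.

## Recovery benchmark and scale choices

The package-scale benchmark (also what `scripts/acceptance.py` reruns) uses
the generator defaults with first-round cut N = 500, per-track K = 50,
threshold 3 of 4 tracks — a deliberate desk-scale reduction of a
compendium-sized analysis (hundreds of studies, N = 5000), chosen so a full
run takes a few minutes on one core while keeping every stage's structure
intact.  With 40 embedded housekeeping genes and K = 50, each track's list
necessarily contains some non-housekeeping fillers; the consensus threshold
removes most of them because filler identity decorrelates across tracks.
Evaluation draws a held-out 24-sample count matrix and compares the 13
lowest-noise embedded-stable genes against the 13 lowest-noise responsive
genes (a "commonly used reference genes"-style set: decent but condition
dependent), reporting the top-10 occupancy of the stable set under both the
SD and the Gini rankings.

## Numerical conventions

* Population SD (divisor n) everywhere, including the first-round ranking.
* Median polish iterates until the largest removed median is below 1e-8
  (≤ 100 iterations); exactly additive blocks converge in one sweep with
  zero residuals.
* Quantile normalization resolves ties by averaging the tied target
  quantiles, so tied input values stay tied.
* All orderings (rankings, consensus reports, aggregation tie-breaks) are
  made deterministic by lexicographic gene-id tie-breaks.
* Every random draw descends from a single integer seed via hashed,
  stage-tagged `SeedSequence` children; reruns are bit-identical, which the
  suite checks by checksumming entire run directories.

## Known limitations

* The RMA background and VSN parameter estimators are simplified relative to
  their eponymous model-based originals (see above); they share the
  originals' qualitative behavior, which is what the variance-ranking
  pipeline consumes.
* The detection-floor criterion is a proxy for platform detection calls.
* Footrule is the only production distance (a Kendall-style alternative
  would change optima on ties); the optimizer is stochastic, and although
  convergence is monitored, global optimality is only guaranteed where the
  exhaustive oracle is feasible.
* Gini on log-scale data is sensitive to values near zero; the linear-scale
  convention used in reports is stated in every output.
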