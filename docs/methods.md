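# Methods

## Single-sample enrichment

The scoring core estimates, per sample and gene set, how concentrated the
set's genes are at the extremes of the sample's expression profile.

**GSVA-style score.**  For gene *i* with expression `x_ij` across *n*
samples, the kernel CDF statistic is

    z_ij = (1/n) Σ_k Φ((x_ij − x_ik) / h_i),   h_i = s_i / 4,

with `s_i` the gene's across-sample standard deviation (ddof = 1) and Φ the
standard normal CDF.  This nonparametric normalisation puts all genes on a
common (0, 1) scale and makes the score invariant to any global rescaling of
the input, because `h_i` scales with `s_i`.  Zero-variance genes are given a
flat 0.5 rather than dropped so that gene universes remain aligned across
sets.  Within each sample, genes are ranked by `z` descending (ties broken
by first occurrence in gene order — deterministic), and position `p` of `N`
carries the symmetric rank weight `|N/2 − p|^tau` (default `tau = 1`),
largest at both extremes of the profile.  A walk down the ranked list adds
the normalised rank weight for in-set genes and subtracts `1/(N − m)` for
out-of-set genes (`m` = set size); the score is the maximum positive plus
the minimum negative deviation of the walk ("max-diff").  Because in-set
increments and out-of-set decrements each sum to one, each deviation is
already normalised by its maximum attainable magnitude, so the score lies
in [−1, 1] *exactly*; the implementation clips the ~1e−16 of floating-point
cumsum dust.  Degenerate guard: a set whose total rank weight is zero (only
possible for a single-gene set landing exactly at rank N/2) contributes no
increments and scores from decrements alone.

**ssGSEA-style score.**  Genes are ranked by raw expression within the
sample (top gene has rank `N`); the score is the summed difference between
the rank-weighted in-set ECDF (weights `rank^alpha`, default `alpha = 0.25`)
and the unweighted out-of-set ECDF.  It is unbounded unless the whole table
is divided by its max − min (`normalize=True`), which pins the table range
to 1.  Linear (FPKM-like) inputs are log2(x+1)-transformed before either
engine; microarray inputs are assumed already log-scale and not
re-transformed.

Both engines are verified against independent brute-force enumerations
(explicit kernel summation and walk loops) to 1e−10 on randomised inputs.

## Composite scores

- **BBB score** — the arithmetic mean of the endothelial, astrocyte and
  pericyte GSVA scores, no renormalisation; it therefore stays within the
  [min, max] of its constituents and within [−1, 1].
- **ESTIMATE-like** — stromal and immune ssGSEA scores with a shared range
  normalisation, their sum, and tumor purity
  `cos(0.6049872018 + 0.0001467884 · combined)` clamped to [0, 1].  The two
  cosine constants come from the purity publication that fitted them on a
  specific platform; the map is applied to any input with a logged warning
  and should be read as indicative off-platform.
- **IMPRES-like** — per pair (A, B), `q = log10((A + c)/(B + c))` on
  linear-scale expression with pseudocount `c = 1`; q is z-standardised
  across samples (population SD; zero-variance pairs contribute 0) and
  summed over pairs.  The published description of the continuous variant is
  ambiguous about the exact quotient normalisation, so both the pseudocount
  and the standardisation are explicit parameters.  The pseudocount breaks
  exact scale invariance; for expression ≥ 100 the score moves by < 0.05
  per sample under a tenfold global rescale.

## Association and survival analytics

Spearman correlation uses average ranks with a two-sided t-approximation
p-value (exact permutation is impractical at cohort sizes).  Group
comparisons dispatch on the number of levels: two → Welch t-test,
three or more → one-way ANOVA.  PCA operates on z-scored score columns
(the scores live on different scales).  The gene screen keeps genes whose
Spearman rho with the BBB score *strictly* exceeds the threshold
(default 0.7); over-representation uses the upper-tail hypergeometric test
with the measured genes as universe and Benjamini–Hochberg adjustment.

Survival: median splits send ties to "high"; Kaplan–Meier, log-rank and
Cox fits are delegated to lifelines (Efron tie handling, Wald inference;
Newton convergence tightened to 1e−12 so coefficients match direct partial-
likelihood maximisation to ~1e−9).  The time-dependent ROC is the
cumulative-case / dynamic-control estimator with Kaplan–Meier weighting
within marker strata:

    sens(c) = [1 − S_{M>c}(t*)] P(M>c) / [1 − S(t*)]
    spec(c) = 1 − S_{M>c}(t*) P(M>c) / S(t*)

The horizon defaults to the cohort's median observed survival time.  The
ROC path is traced in descending threshold order and isotonised by a
cumulative maximum — this removes floating-point dust and the known mild
non-monotonicity of the conditional-KM estimator — before trapezoid
integration.  With no censoring before the horizon the AUC equals the
Mann–Whitney AUC of the binary event-by-horizon outcome exactly, which is
asserted as an oracle test.

## The synthetic cohort generator

Each sample is a convex mixture of seven components: six brain-resident
cell types (endothelial cells, astrocytes, pericytes, microglia, neurons,
oligodendrocytes) plus a tumor component.  A latent BBB-alteration factor
`u ~ Uniform(0, 1)` per sample tilts a Dirichlet draw by scaling its Gamma
components:

    f_c ∝ Gamma(α_c) · exp(λ_c · bbb_link · tilt_scale · (2u − 1))

with tilt directions λ = +1 for the three BBB cells, −1 for the neural
lineage (neurons, oligodendrocytes), +1/2 for other stromal/immune
residents (microglia, or any extra type added to the catalog) and −1/2 for
tumor.  One knob (`bbb_link`, default 0.8) therefore controls the
collinearity of the BBB cell fractions and their coupling to purity, grade
and hazard.  Marker genes (50 per type, disjoint blocks) are elevated by
`signature_effect` = 2 log2 units in their own cell type over a shared
background; expression is the linear mixture of the reference profiles
with multiplicative log-normal noise (log2 SD 0.5).  Tumor purity is the
tumor mixing fraction.  WHO grade is the tertile of `u`.  Survival times
are exponential with rate `(1/1000) · exp(hazard_beta · (u − 0.5))` per
day, so the planted `hazard_beta` (default 1.0) is exactly the Cox
estimand on `u`; censoring is independent exponential with rate 2.5e−4,
giving roughly 20% censoring at the default hazard.  Age and KPS come from
a Gaussian copula with rank correlation ≈ 0.3 with `u`; IDH-mutant and
1p/19q-codeleted labels become less likely as `u` rises.

Cohort-level parameters: 685 samples (the size of a combined
lower-grade + glioblastoma reference cohort) and 2000 genes by default.
The Dirichlet concentrations (tumor 20, BBB cells 5 each, other residents
2 each) and `tilt_scale` = 2.5 were fixed once, by pilot simulation, to
give a wide but realistic purity spread (≈ 0.05–0.85, mean ≈ 0.45) with
the BBB cells' variation dominated by the shared factor rather than by
Dirichlet noise.  The stromal compartment set is the union of the
positively tilted residents' markers and the immune set the microglia-like
markers, mirroring how general stromal/immune signatures relate to the
planted populations.

**What the generator emulates, and what it does not.**  It reproduces the
statistical structure the analysis presumes — collinear BBB fractions,
purity inversely tied to stromal content, grade and hazard rising with the
factor — with clean exponential survival, a single noise scale, no batch
effects, no platform differences, and marker blocks that are perfectly
disjoint and fully measured.  Passing recovery tests therefore show the
pipeline is self-consistent and well-powered under its own assumptions,
not that real cohorts behave this way.

Two generator properties worth knowing:

- *Compositional closure.*  Because fractions live on a simplex, setting
  `bbb_link = 0` does not make cell scores independent: a small negative
  residual correlation (≈ −0.2 at the score level) remains as the
  components compete for the simplex.  The null tests assert that the
  *positive* collinearity vanishes.
- *Per-gene signal ceiling.*  A marker's bulk log2 signal is
  `log2(1 + (2^effect − 1) · f_c)`, at most ~2 log2 units at the default
  4-fold effect, with realistic fraction spreads its SD is ≈ 0.3 — against
  per-gene noise SD 0.5 this caps a single gene's Spearman correlation
  with the BBB score near 0.5 (≈ 0.7 even for a fraction spanning the full
  unit interval).  Set-level scores average this noise away, which is why
  the BBB score recovers the factor at rho ≈ 0.95 while the per-gene
  rho > 0.7 screen recovers almost no individual markers at these effect
  and noise levels.  The screen's sensitivity is reported honestly by the
  acceptance suite rather than tuned to a target.

## Numerical and design choices

- Probe collapse keeps the probe whose across-sample mean is the median of
  the probe means (even counts: the lower central probe) — a real measured
  row, never an average; ties break by input order.
- Rank ties in both engines break by first occurrence; median-split ties go
  "high"; largest-signature ties break lexicographically by set name.  All
  tie rules are deterministic, so identical inputs give identical outputs.
- Degenerate inputs are errors, not silent results: empty cohorts after
  missing-data exclusion, sets covering the whole gene universe, constant
  score vectors at a median split, constant covariates in a Cox model,
  horizons with no events.  Exceptions: a no-event Kaplan–Meier cohort
  returns the constant-1 curve with a warning, and checkpoint pairs with
  unmeasured genes are dropped with a log message.
- Analysis problem sizes in the test suite (200 samples for structural
  recovery, 300 for the grade trend, 500 × 10 replicates for hazard
  recovery) were chosen as the smallest cohorts at which the planted
  effects are decisively powered.

## Known limitations

- GSVA scoring assumes log-scale input for RNA-seq; no Poisson-kernel
  variant for raw counts is provided.
- The purity cosine map is a platform-specific fit applied generically.
- The bundled ECM list and checkpoint-pair list are labelled synthetic
  placeholders of the right cardinality; real analyses should supply the
  published lists.
- The time-dependent ROC implements only the KM-weighted variant (recorded
  in output metadata), not nearest-neighbour smoothing or IPCW weighting.
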