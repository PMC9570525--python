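# bbbscore

Scoring blood–brain-barrier (BBB) alteration in glioma bulk transcriptomes,
and testing what such scores can recover, end to end.

Gliomas remodel the vascular interface of the brain: the endothelial cells,
astrocytes and pericytes that form the BBB infiltrate the tumor
microenvironment (TME) in tightly coupled proportions, and their joint
abundance tracks tumor grade, purity and patient survival.  `bbbscore`
implements the full analysis pipeline for quantifying this from a
genes × samples expression matrix:

- **Single-sample enrichment** of cell-type signatures, two engines:
  a GSVA-style score (Gaussian-kernel CDF normalisation, symmetric rank
  statistic, weighted Kolmogorov–Smirnov-like walk, "max-diff" scoring in
  [−1, 1]) and an ssGSEA-style score (rank-weighted ECDF difference).
- **The BBB score**: for sample *j*,

  `BBB_j = (GSVA_j(endothelial) + GSVA_j(astrocytes) + GSVA_j(pericytes)) / 3`

- **ESTIMATE-like TME scores**: stromal and immune ssGSEA scores, their sum,
  and tumor purity via the fitted cosine map
  `purity = cos(0.6049872018 + 0.0001467884 · (stromal + immune))`.
- **A continuous checkpoint-pair (IMPRES-like) score**: per gene pair
  (A, B), `q = log10((A + 1)/(B + 1))`, z-standardised across samples and
  summed over 15 pairs.
- **Association analytics**: Spearman/Pearson correlation, Welch t /
  one-way ANOVA dispatch, PCA of cell-type scores, the rho > 0.7 gene
  screen, hypergeometric over-representation with Benjamini–Hochberg
  adjustment, extracellular-matrix gene ranking.
- **Survival analytics**: median dichotomisation, Kaplan–Meier curves,
  log-rank tests, Cox proportional-hazards models (Efron ties),
  KM-weighted cumulative/dynamic time-dependent ROC, classical ROC.
- **A synthetic-cohort generator** that plants the ground truth this whole
  analysis presumes — convex cell-type mixtures whose BBB constituents
  share a latent alteration factor, purity inversely tied to stromal
  content, grade rising with the factor, and survival times with a known
  log-hazard per unit factor — so every stage is testable without any
  download.

Inputs are plain TSV/GMT files (expression matrices, clinical tables,
gene-set collections, gene-pair lists); outputs are TSV/JSON with scoring
parameters recorded in sidecars.

## Worked example

Simulate a 200-sample cohort with planted truth, score it, and ask whether
the structure comes back:

```python
import itertools
from scipy.stats import pearsonr, spearmanr

from bbbscore import enrichment, io_formats, tme_scores
from bbbscore.survival import cox_fit, dichotomize_median, logrank_test
from bbbscore.synthetic_data import GeneratorConfig, simulate_cohort

cfg = GeneratorConfig(n_samples=200, seed=1)
matrix, clinical, truth = simulate_cohort(cfg)
logm = io_formats.log_transform(matrix)                      # log2(FPKM + 1)
table = enrichment.score_all_cell_types(logm, truth.signatures, cfg.cell_types)
bbb = tme_scores.bbb_score(table)

rho, _ = spearmanr(truth.bbb_factor, bbb)
print(f"latent factor vs BBB score: Spearman rho = {rho:.3f}")
for a, b in itertools.combinations(
    ("endothelial cells", "astrocytes", "pericytes"), 2
):
    r, _ = pearsonr(table.scores[a], table.scores[b])
    print(f"{a} vs {b}: Pearson r = {r:.3f}")

groups = dichotomize_median(bbb.to_numpy())
stat, p = logrank_test(clinical["os_time"], clinical["os_event"], groups)
print(f"median-split log-rank: chi2 = {stat:.2f}, p = {p:.2e}")

fit = cox_fit(clinical["os_time"], clinical["os_event"],
              truth.bbb_factor.to_frame("u").reset_index(drop=True))
row = fit.table.iloc[0]
print(f"Cox on latent factor: log HR = {row['coef']:.3f} "
      f"(planted 1.0), 95% CI [{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
```

prints

```
latent factor vs BBB score: Spearman rho = 0.956
endothelial cells vs astrocytes: Pearson r = 0.687
endothelial cells vs pericytes: Pearson r = 0.714
astrocytes vs pericytes: Pearson r = 0.733
median-split log-rank: chi2 = 3.15, p = 7.59e-02
Cox on latent factor: log HR = 0.656 (planted 1.0), 95% CI [1.14, 3.25]
```

The composite BBB score recovers the planted alteration factor almost
perfectly (rho 0.96), and the three constituent cell scores show the
hallmark pairwise collinearity.  The Cox fit recovers the planted unit
log-hazard within its confidence interval (the CI shown is on the
hazard-ratio scale); at n = 200 the median-split log-rank test is
underpowered (p 0.08) — the survival checks in the test suite use n = 500,
where the split separates decisively.

The same pipeline is available from the shell:

```sh
bbbscore simulate --outdir cohort --seed 1 --n-samples 200
bbbscore score --expression cohort/expression.tsv \
    --cell-signatures cohort/planted_signatures.gmt \
    --stromal-immune cohort/stromal_immune.gmt --outdir scores
bbbscore analyze --scores scores/scores.tsv --clinical cohort/clinical.tsv \
    --expression cohort/expression.tsv --outdir analysis
```

Editable gene-set fixtures (six brain cell-type signatures, stromal/immune
sets, a checkpoint list, a 249-gene ECM placeholder and a 15-pair
checkpoint-pair list — the latter two synthetic stand-ins for
user-supplied lists) ship under `bbbscore/data/`.

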