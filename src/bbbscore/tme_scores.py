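"""Composite tumor-microenvironment scores.

* **BBB score** — per-sample mean of the GSVA infiltration scores of the
  three blood-brain-barrier constituent cell types (endothelial cells,
  astrocytes, pericytes).  Because those three scores are strongly collinear
  in glioma, their average summarises the degree of BBB alteration in one
  dimensionless number in [-1, 1].
* **ESTIMATE-like scores** — stromal and immune ssGSEA scores, their sum,
  and a tumor-purity estimate obtained from the fitted cosine map
  ``purity = cos(a + b * combined)`` of the original purity publication.
* **Continuous IMPRES-like score** — instead of binary gene-pair indicators,
  each checkpoint gene pair contributes a standardised log10 expression
  quotient; the per-sample sum is the score (higher = more favourable
  predicted checkpoint-blockade response).
* **Immune-cell infiltration** — GSVA scores of immune cell-type signatures
  (dendritic cells, M2 macrophages, ...).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import ScoreTable, gsva_score, ssgsea_score
from .io_formats import ExpressionMatrix
from .signatures import GenePairList, GeneSet, SignatureCollection

logger = logging.getLogger(__name__)

#: Constituent cell types of the blood-brain barrier (name prefixes).
BBB_CELL_TYPES = ("endothelial", "astrocyte", "pericyte")

# Cosine purity fit from the original stromal/immune purity publication
# (platform-specific fit; applied here to any platform with a warning).
ESTIMATE_PURITY_INTERCEPT = 0.6049872018
ESTIMATE_PURITY_SLOPE = 0.0001467884


def _find_column(table: ScoreTable, prefix: str) -> str:
    matches = [
        c for c in table.score_names if c.strip().lower().startswith(prefix)
    ]
    if not matches:
        raise KeyError(
            f"score table lacks a column for {prefix!r} "
            f"(have {table.score_names!r})"
        )
    return matches[0]


def bbb_score(table: ScoreTable) -> pd.Series:
    """Mean of the endothelial, astrocyte and pericyte GSVA columns.

    Columns are located by case-insensitive prefix ("endothelial",
    "astrocyte", "pericyte"); a missing constituent is a named error.  No
    renormalisation is applied, so the result stays within [min, max] of its
    three constituents for every sample.
    """
    cols = [_find_column(table, p) for p in BBB_CELL_TYPES]
    out = table.scores[cols].mean(axis=1)
    out.name = "bbb_score"
    return out


def estimate_like(
    m: ExpressionMatrix,
    stromal_set: GeneSet,
    immune_set: GeneSet,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Stromal/immune ssGSEA scores, their sum, and cosine-mapped purity.

    Both sets are scored jointly with a shared range normalisation.  Purity
    is ``cos(a + b * combined)`` clamped to [0, 1]; the cosine constants come
    from a platform-specific fit, so purity values on other platforms are
    indicative rather than calibrated (a warning is logged).
    """
    logger.warning(
        "purity cosine constants come from a platform-specific fit; "
        "treat purity on other platforms as indicative"
    )
    table = ssgsea_score(
        m,
        SignatureCollection([
            GeneSet("stromal", stromal_set.genes, "stromal"),
            GeneSet("immune", immune_set.genes, "immune"),
        ]),
        alpha=alpha,
        normalize=True,
    )
    out = table.scores.copy()
    out["combined"] = out["stromal"] + out["immune"]
    purity = np.cos(
        ESTIMATE_PURITY_INTERCEPT + ESTIMATE_PURITY_SLOPE * out["combined"]
    )
    out["purity"] = purity.clip(0.0, 1.0)
    return out


def impres_like(
    m: ExpressionMatrix, pairs: GenePairList, pseudocount: float = 1.0
) -> tuple[pd.Series, int]:
    """Continuous checkpoint-pair score: sum of standardised log-quotients.

    For each pair (A, B), ``q = log10((A + c) / (B + c))`` on linear-scale
    expression with pseudocount ``c``; q is z-standardised across samples
    (population sd; a zero-variance pair contributes 0) and the per-sample
    sum over pairs is the score.  Pairs with either gene unmeasured are
    dropped with a log message; returns the score and the number of pairs
    actually used.
    """
    if m.log_transformed:
        raise ValueError("IMPRES-like score expects linear-scale expression")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    measured = set(m.gene_ids)
    usable = [(a, b) for a, b in pairs.pairs if a in measured and b in measured]
    dropped = len(pairs) - len(usable)
    if dropped:
        logger.info("dropping %d pair(s) with unmeasured genes", dropped)
    if not usable:
        raise ValueError("no checkpoint pair has both genes measured")
    total = np.zeros(len(m.sample_ids))
    for a, b in usable:
        q = np.log10(
            (m.values.loc[a].to_numpy() + pseudocount)
            / (m.values.loc[b].to_numpy() + pseudocount)
        )
        sd = q.std()
        if sd > 0:
            total += (q - q.mean()) / sd
    score = pd.Series(total, index=m.values.columns, name="impres_like")
    return score, len(usable)


def immune_cell_scores(
    m: ExpressionMatrix, immune_sets: SignatureCollection, tau: float = 1.0
) -> ScoreTable:
    """GSVA infiltration score per immune cell-type signature."""
    return gsva_score(m, immune_sets, tau=tau)
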