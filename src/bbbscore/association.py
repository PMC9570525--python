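"""Correlation, group comparison, PCA, gene screening and over-representation.

These are the association stages linking infiltration scores to clinical
covariates and to individual genes: Spearman/Pearson correlation with a
t-approximation p-value, Welch t-test / one-way ANOVA dispatch on group
count, PCA of the cell-type score matrix, a correlation screen for genes
tracking the BBB score (default cut rho > 0.7, strict), hypergeometric
over-representation with Benjamini-Hochberg adjustment, and ranking of
extracellular-matrix genes by their correlation with the BBB score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .enrichment import ScoreTable
from .io_formats import ExpressionMatrix
from .signatures import GeneSet, SignatureCollection


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass
class PCAResult:
    """Loadings (components x scores), sample coordinates, variance fractions."""

    loadings: np.ndarray
    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Spearman or Pearson correlation with two-sided t-approximation p.

    Spearman is Pearson on average ranks (ties averaged).  Requires n >= 3
    and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(rho), float(p), len(x), method)


def correlation_matrix(
    table: ScoreTable, refs: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every score column with every reference vector.

    ``refs`` is a samples-by-references DataFrame; only shared samples are
    used and at least three are required.  Returns (rho, p) DataFrames with
    scores as rows and references as columns.
    """
    shared = table.scores.index.intersection(refs.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    s = table.scores.loc[shared].sort_index()
    r = refs.loc[shared].sort_index()
    rho = pd.DataFrame(index=s.columns, columns=r.columns, dtype=float)
    pval = rho.copy()
    for sc in s.columns:
        for rc in r.columns:
            res = correlate(s[sc], r[rc], method=method)
            rho.loc[sc, rc] = res.rho
            pval.loc[sc, rc] = res.p_value
    return rho, pval


def group_compare(values, groups) -> tuple[float, float, str]:
    """Two groups: Welch t-test; three or more: one-way ANOVA.

    Returns (statistic, p_value, test_name).  Every group needs at least two
    observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g] for g in levels]
    for g, arr in zip(levels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if len(levels) == 2:
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return float(stat), float(p), "welch_t"
    stat, p = stats.f_oneway(*arrays)
    return float(stat), float(p), "anova"


def pca_scores(table: ScoreTable, k: int = 2) -> PCAResult:
    """PCA of z-scored score columns (scores live on different scales).

    Loadings are orthonormal and explained-variance fractions non-increasing.
    """
    data = table.scores.to_numpy(dtype=float)
    if k > data.shape[1]:
        raise ValueError(f"k={k} exceeds number of score columns {data.shape[1]}")
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant score column; cannot z-score for PCA")
    zs = (data - data.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(zs)
    coordinates = pd.DataFrame(
        coords,
        index=table.scores.index,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return PCAResult(pca.components_, coordinates, pca.explained_variance_ratio_)


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (vectorised scipy rankdata)."""
    return stats.rankdata(x, axis=-1)


def spearman_vs_vector(
    m: ExpressionMatrix, ref: pd.Series, drop_constant: bool = True
) -> pd.Series:
    """Spearman rho of every gene against a per-sample reference vector.

    Vectorised: ranks each gene row and the reference, then computes the
    Pearson correlation of the ranks.  Constant genes are dropped (their
    correlation is undefined).
    """
    shared = m.values.columns.intersection(ref.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    x = m.values[shared].to_numpy(dtype=float)
    y = ref.loc[shared].to_numpy(dtype=float)
    keep = np.ptp(x, axis=1) > 0
    if drop_constant:
        x = x[keep]
        index = m.values.index[keep]
    else:
        if not keep.all():
            raise ValueError("constant gene rows present")
        index = m.values.index
    rx = _rank_matrix(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    num = rx @ ry
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    return pd.Series(num / den, index=index, name="rho")


def gene_screen(
    m: ExpressionMatrix, bbb: pd.Series, rho_threshold: float = 0.7
) -> pd.DataFrame:
    """Genes whose Spearman rho with the BBB score strictly exceeds the cut.

    Returns a DataFrame (gene_id index, ``rho`` column) sorted by rho
    descending.  The default threshold 0.7 selects only strongly tracking
    genes; a gene at exactly the threshold is excluded.
    """
    rho = spearman_vs_vector(m, bbb)
    hits = rho[rho > rho_threshold].sort_values(ascending=False)
    return hits.to_frame()


def hypergeometric_ora(
    gene_list, universe, sets: SignatureCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    ``gene_list`` must be a subset of ``universe``; each set is intersected
    with the universe before testing.  Returns rows sorted by raw p with
    columns: set, overlap, set_size, universe_size, list_size, p_value,
    p_adjusted.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    glist = set(gene_list)
    stray = glist - uni
    if stray:
        raise ValueError(f"gene list not within universe: {sorted(stray)[:5]!r}")
    M, n_list = len(uni), len(glist)
    rows = []
    for s in sets:
        members = set(s.genes) & uni
        k = len(members & glist)
        # P(X >= k) for X ~ Hypergeom(M, |set|, |list|)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_list))
        rows.append(
            {
                "set": s.name,
                "overlap": k,
                "set_size": len(members),
                "universe_size": M,
                "list_size": n_list,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def ecm_ranking(
    m: ExpressionMatrix,
    ecm_genes: GeneSet,
    bbb: pd.Series,
    top_pos: int = 20,
    top_neg: int = 10,
) -> pd.DataFrame:
    """Extracellular-matrix genes most correlated with the BBB score.

    Ranks the measured ECM genes by Spearman rho against the BBB score and
    returns the ``top_pos`` most positive and ``top_neg`` most negative,
    signs preserved, with a ``direction`` column.
    """
    measured = [g for g in ecm_genes.genes if g in set(m.gene_ids)]
    if len(measured) < top_pos + top_neg:
        raise ValueError(
            f"only {len(measured)} ECM genes measured; "
            f"need >= {top_pos + top_neg}"
        )
    sub = ExpressionMatrix(m.values.loc[measured], m.log_transformed)
    rho = spearman_vs_vector(sub, bbb).sort_values(ascending=False)
    top = rho.head(top_pos).to_frame()
    top["direction"] = "positive"
    bottom = rho.tail(top_neg).to_frame()
    bottom["direction"] = "negative"
    return pd.concat([top, bottom])
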