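"""Single-sample gene-set enrichment: GSVA-style and ssGSEA-style scores.

The GSVA-style score estimates, per sample and gene set, how concentrated
the set's genes are at the top (or bottom) of that sample's expression
profile after a nonparametric across-sample normalisation:

1. **Kernel CDF statistic.**  Each gene's expression profile across samples
   is converted to a smoothed empirical CDF value using a Gaussian kernel,

       z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i),     h_i = s_i / 4,

   with s_i the gene's across-sample standard deviation.  This places every
   gene on a common (0,1) scale regardless of its absolute expression level
   and makes the score invariant to global rescaling of the input.
   Zero-variance genes receive a flat 0.5 so gene universes stay aligned.
2. **Symmetric rank statistic.**  Within each sample, genes are ranked by z
   (descending, ties by first occurrence); the rank weight is
   |N/2 - rank|^tau, largest at both extremes of the profile.
3. **Weighted random walk.**  Walking down the ranked list, in-set genes add
   their normalised rank weight and out-of-set genes subtract 1/(N - m).
   The score is the maximum positive deviation plus the minimum negative
   deviation of the walk ("max-diff" form); because in-set increments sum to
   1 and out-set decrements sum to 1, each deviation is already normalised
   by its maximum attainable magnitude and the score lies in [-1, 1].

The ssGSEA-style score ranks genes by raw expression within the sample and
accumulates the difference between the rank-weighted in-set ECDF (weights
rank^alpha) and the unweighted out-of-set ECDF; it is unbounded unless the
whole table is rescaled by its range (``normalize=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import ExpressionMatrix
from .signatures import GeneSet, SignatureCollection

__all__ = [
    "ScoreTable",
    "kernel_cdf_statistic",
    "gsva_score",
    "ssgsea_score",
    "score_all_cell_types",
    "write_score_table",
]

#: Gaussian-kernel bandwidth is the gene's standard deviation divided by this.
KERNEL_BANDWIDTH_DIVISOR = 4.0


@dataclass
class ScoreTable:
    """Samples-by-scores table with per-column method provenance.

    ``scores`` is a DataFrame indexed by sample id; ``methods`` maps each
    score column to ``"gsva"`` or ``"ssgsea"``.  GSVA columns lie in
    [-1, 1]; ssGSEA columns are unbounded unless normalised.
    """

    scores: pd.DataFrame
    methods: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("score table contains missing values")
        for col, meth in self.methods.items():
            if meth == "gsva":
                v = self.scores[col].to_numpy()
                if (v < -1 - 1e-9).any() or (v > 1 + 1e-9).any():
                    raise ValueError(f"gsva column {col!r} outside [-1, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def score_names(self) -> list[str]:
        return list(self.scores.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.scores[name]

    def join(self, other: "ScoreTable") -> "ScoreTable":
        """Column-wise concatenation on identical sample ids."""
        if not self.scores.index.equals(other.scores.index):
            raise ValueError("sample ids differ between score tables")
        return ScoreTable(
            pd.concat([self.scores, other.scores], axis=1),
            {**self.methods, **other.methods},
            {**self.params, **other.params},
        )


def kernel_cdf_statistic(m: ExpressionMatrix, chunk_size: int = 128) -> pd.DataFrame:
    """Gaussian-kernel smoothed CDF of each gene's across-sample profile.

    Requires at least two samples (a single sample has no across-sample
    distribution to normalise against).  Returns a genes-by-samples
    DataFrame with all values in (0, 1); constant genes map to 0.5.
    """
    x = m.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("kernel CDF statistic needs >= 2 samples")
    sd = x.std(axis=1, ddof=1)
    z = np.empty_like(x)
    for start in range(0, n_genes, chunk_size):
        stop = min(start + chunk_size, n_genes)
        block = x[start:stop]
        bsd = sd[start:stop]
        ok = bsd > 0
        h = np.where(ok, bsd / KERNEL_BANDWIDTH_DIVISOR, 1.0)
        diff = (block[:, :, None] - block[:, None, :]) / h[:, None, None]
        zb = ndtr(diff).mean(axis=2)
        zb[~ok] = 0.5
        z[start:stop] = zb
    return pd.DataFrame(z, index=m.values.index, columns=m.values.columns)


def _set_indicator(genes: pd.Index, gene_set: GeneSet) -> np.ndarray:
    members = set(gene_set.genes)
    ind = genes.isin(members)
    m = int(ind.sum())
    if m == 0:
        raise ValueError(f"set {gene_set.name!r} has no genes in the matrix")
    if m >= len(genes):
        raise ValueError(
            f"set {gene_set.name!r} covers every measured gene; "
            "out-of-set decrement is undefined"
        )
    return ind


def _walk_scores(
    order: np.ndarray, inset: np.ndarray, weights: np.ndarray, n_out: int
) -> np.ndarray:
    """Max-diff random-walk score for one gene set across all samples.

    ``order`` is (N, n_samples) gene indices sorted by decreasing statistic,
    ``weights`` the per-position rank weights, ``inset`` the set-membership
    indicator in gene order.
    """
    ind_sorted = inset[order]  # (N, n_samples)
    w = weights[:, None] * ind_sorted
    denom = w.sum(axis=0)
    inc = np.divide(w, denom, out=np.zeros_like(w), where=denom > 0)
    dec = (~ind_sorted) / n_out
    walk = np.cumsum(inc - dec, axis=0)
    pos = np.maximum(walk.max(axis=0), 0.0)
    neg = np.minimum(walk.min(axis=0), 0.0)
    # each deviation is normalised by its attainable maximum (1), so the
    # score is in [-1, 1] exactly; clip floating-point cumsum dust
    return np.clip(pos + neg, -1.0, 1.0)


def gsva_score(
    m: ExpressionMatrix, sets: SignatureCollection, tau: float = 1.0
) -> ScoreTable:
    """GSVA-style enrichment of each set in each sample; values in [-1, 1].

    ``tau`` exponentiates the symmetric rank weight |N/2 - rank|; tau = 1 is
    the conventional default.  Every set must already be restricted to
    measured genes and leave at least one gene outside the set.
    """
    z = kernel_cdf_statistic(m).to_numpy()
    genes = m.values.index
    n_genes = len(genes)
    # stable descending sort => rank ties broken by first occurrence
    order = np.argsort(-z, axis=0, kind="stable")
    positions = np.arange(1, n_genes + 1, dtype=float)
    weights = np.abs(n_genes / 2.0 - positions) ** tau
    cols = {}
    for gene_set in sets:
        ind = _set_indicator(genes, gene_set)
        n_out = n_genes - int(ind.sum())
        cols[gene_set.name] = _walk_scores(order, ind, weights, n_out)
    df = pd.DataFrame(cols, index=m.values.columns)
    df.index.name = "sample_id"
    return ScoreTable(df, {c: "gsva" for c in df.columns}, {"tau": tau})


def ssgsea_score(
    m: ExpressionMatrix,
    sets: SignatureCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreTable:
    """ssGSEA-style enrichment: rank-weighted in-set vs out-set ECDF gap.

    Genes are ranked by raw expression within each sample (highest gene has
    rank N); in-set genes are weighted rank^alpha.  With ``normalize`` the
    whole table is divided by its (max - min), pinning the range to 1.
    """
    x = m.values.to_numpy(dtype=float)
    genes = m.values.index
    n_genes, n_samples = x.shape
    order = np.argsort(-x, axis=0, kind="stable")  # (N, n) descending
    positions = np.arange(1, n_genes + 1, dtype=float)
    rank_at_position = n_genes - positions + 1.0  # top of list has rank N
    w_pos = rank_at_position**alpha
    cols = {}
    for gene_set in sets:
        ind = _set_indicator(genes, gene_set)
        n_out = n_genes - int(ind.sum())
        ind_sorted = ind[order]
        w = w_pos[:, None] * ind_sorted
        denom = w.sum(axis=0)
        ecdf_in = np.cumsum(w, axis=0) / denom
        ecdf_out = np.cumsum(~ind_sorted, axis=0) / n_out
        cols[gene_set.name] = (ecdf_in - ecdf_out).sum(axis=0)
    df = pd.DataFrame(cols, index=m.values.columns)
    df.index.name = "sample_id"
    if normalize:
        spread = float(df.to_numpy().max() - df.to_numpy().min())
        if spread == 0:
            raise ValueError("cannot normalize: all ssGSEA scores identical")
        df = df / spread
    return ScoreTable(
        df,
        {c: "ssgsea" for c in df.columns},
        {"alpha": alpha, "normalize": normalize},
    )


def score_all_cell_types(
    m: ExpressionMatrix,
    collection: SignatureCollection,
    cell_types,
    tau: float = 1.0,
    min_genes: int = 2,
) -> ScoreTable:
    """One GSVA column per requested cell type, in the requested order.

    For each cell type the largest matching signature in ``collection`` is
    chosen and restricted to measured genes before scoring.
    """
    from .signatures import restrict_to_measured, select_largest_signature

    chosen = []
    for ct in cell_types:
        sig = select_largest_signature(collection, ct)
        sig = restrict_to_measured(sig, m, min_genes=min_genes)
        chosen.append(GeneSet(ct, sig.genes, sig.category, sig.description))
    table = gsva_score(m, SignatureCollection(chosen), tau=tau)
    return ScoreTable(
        table.scores[list(cell_types)], table.methods, table.params
    )


def write_score_table(table: ScoreTable, path, sidecar: dict | None = None) -> None:
    """Write scores as TSV plus a JSON sidecar recording method provenance."""
    out = table.scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = {"methods": table.methods, "params": table.params}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
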