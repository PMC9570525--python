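"""Reading, writing and hygiene of expression and clinical tables.

Two data-hygiene conventions are applied before any scoring:

* **Probe collapse** — when several microarray probes map to the same gene,
  the probe whose mean intensity across samples is the *median* of the probe
  means is retained, so a real measured row (not an averaged synthetic one)
  represents the gene.  For an even number of probes the lower of the two
  central probes is kept.
* **Missing-data exclusion** — samples lacking any clinical field required by
  an analysis are dropped from that analysis.

Expression matrices are genes-by-samples TSV files (first column gene or
probe identifiers, header row of sample identifiers).  Clinical tables are
sample-per-row TSV files with the literal ``NA`` marking missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names recognised in clinical tables.
CLINICAL_COLUMNS = (
    "sample_id",
    "grade",
    "histology",
    "age",
    "kps",
    "idh_status",
    "codel_1p19q",
    "os_time",
    "os_event",
    "days_to_recurrence",
)


class ExpressionMatrixError(ValueError):
    """Malformed or inconsistent expression input."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples numeric expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) identifier with one column per
        sample.  Must be fully numeric with no missing cells.
    log_transformed
        Whether the values are on a log2 scale.  RNA-seq FPKM inputs are
        expected linear and log2(x+1)-transformed before kernel-based
        scoring; microarray series matrices are typically already log-scale.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionMatrixError(
                f"duplicate gene/probe identifiers: {list(dupes[:5])!r}"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ExpressionMatrixError(
                f"duplicate sample identifiers: {list(dupes[:5])!r}"
            )
        if self.values.isna().any().any():
            raise ExpressionMatrixError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.log_transformed)


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-by-samples matrix from a delimited text file.

    Rows containing any non-numeric cell are rejected (dropped with a
    warning).  Duplicate sample identifiers in the header and empty files are
    hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ExpressionMatrixError(f"empty expression file: {path}")
    sample_ids = header.split(delimiter)[1:]
    if len(sample_ids) != len(set(sample_ids)):
        raise ExpressionMatrixError(f"duplicate sample ids in header of {path}")

    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.empty:
        raise ExpressionMatrixError(f"expression file has no data rows: {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "dropping %d row(s) with non-numeric cells: %s",
            int(bad.sum()),
            list(numeric.index[bad][:5]),
        )
        numeric = numeric.loc[~bad]
    if numeric.empty:
        raise ExpressionMatrixError(f"no numeric rows in {path}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix as TSV with full float precision (round-trip safe)."""
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=delimiter, float_format="%.17g")


def read_probe_map(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column probe-to-gene map.

    Every probe must map to exactly one gene (many probes per gene are fine).
    Returns a Series indexed by probe id with gene id values.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"probe map must have exactly 2 columns, got {df.shape[1]}")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dupes = probes[probes.duplicated()].unique()
        raise ValueError(f"probes mapping to multiple genes: {list(dupes[:5])!r}")
    return pd.Series(genes.values, index=probes.values, name="gene_id")


def collapse_probes(m: ExpressionMatrix, probe_map: pd.Series) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by the median-probe rule.

    For each gene with *k* probes the retained row is the probe whose mean
    across samples is the median of the k probe means; for even k the lower
    of the two central probes is kept.  Genes with a single probe pass
    through unchanged.  Ties between equal probe means are broken by probe
    order in the input matrix (stable sort), keeping the rule deterministic.
    """
    unmapped = [p for p in m.gene_ids if p not in probe_map.index]
    if unmapped:
        raise KeyError(
            f"{len(unmapped)} probe(s) missing from probe map: {unmapped[:10]!r}"
        )
    means = m.values.mean(axis=1)
    genes = probe_map.loc[m.values.index]
    chosen: list[str] = []
    gene_order: list[str] = []
    for gene, probe_ids in genes.groupby(genes, sort=False).groups.items():
        probe_means = means.loc[probe_ids]
        order = probe_means.sort_values(kind="stable")
        # lower-central element: index (k-1)//2 of the sorted means
        pick = order.index[(len(order) - 1) // 2]
        chosen.append(pick)
        gene_order.append(str(gene))
    out = m.values.loc[chosen].copy()
    out.index = pd.Index(gene_order, name="gene_id")
    return ExpressionMatrix(out, m.log_transformed)


def log_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return log2(x + offset) of a linear-scale matrix.

    Refuses to transform twice; kernel bandwidths and rank statistics
    downstream assume a single, known scale.
    """
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    if offset <= 0:
        raise ValueError("offset must be positive")
    if (m.values.values < 0).any():
        raise ValueError("negative expression values; expected linear scale >= 0")
    return ExpressionMatrix(np.log2(m.values + offset), log_transformed=True)


def read_clinical_table(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a clinical table; ``NA`` cells become missing values.

    Validates unique sample ids, non-negative survival times and 0/1 event
    indicators where present.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must contain a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id values in clinical table")
    for col in ("age", "kps", "os_time", "os_event", "days_to_recurrence"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if "os_time" in df.columns and (df["os_time"].dropna() < 0).any():
        raise ValueError("os_time must be non-negative")
    if "os_event" in df.columns:
        ev = df["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("os_event must be 0 or 1")
    return df


def write_clinical_table(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def exclude_missing(clinical: pd.DataFrame, required_fields) -> pd.DataFrame:
    """Drop samples missing any of ``required_fields``; idempotent.

    Raises if the filter empties the cohort (a sign the wrong fields were
    requested), and logs how many samples were removed otherwise.
    """
    required_fields = list(required_fields)
    missing_cols = [c for c in required_fields if c not in clinical.columns]
    if missing_cols:
        raise KeyError(f"required fields absent from table: {missing_cols!r}")
    if not required_fields:
        return clinical.copy()
    keep = clinical[required_fields].notna().all(axis=1)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"all {len(clinical)} samples missing at least one of {required_fields!r}"
        )
    if n_removed:
        logger.info(
            "excluded %d sample(s) with missing %s", n_removed, required_fields
        )
    return clinical.loc[keep].copy()
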