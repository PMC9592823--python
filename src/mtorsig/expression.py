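"""Expression-matrix containers, I/O and preprocessing.

The common currency of the pipeline is a gene x sample matrix of log-scale
expression values (log2(TPM+1) for RNA-seq, log2 intensities for microarray)
together with a per-sample phenotype table. This module provides the matrix
container, tab-delimited I/O, probe/replicate aggregation, low-information
gene filtering, quantile normalization (with a frozen reference so held-out
samples can be projected onto a training normalization) and per-gene
standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "QuantileReference",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotype_table",
    "aggregate_probes",
    "filter_low_info",
    "quantile_normalize",
    "standardize_genes",
]

#: allowed values of ``ExpressionMatrix.scale_tag``
SCALE_TAGS = ("log2_tpm_plus1", "log2_intensity", "standardized")


class ExpressionError(ValueError):
    """Raised on malformed expression inputs."""


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of finite, log-scale expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers (genes or probes).
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Finite real expression values.
    scale_tag : str
        One of ``log2_tpm_plus1``, ``log2_intensity``, ``standardized``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2_tpm_plus1"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ExpressionError("non-finite values in expression matrix")
        if self.scale_tag not in SCALE_TAGS:
            raise ExpressionError(f"unknown scale_tag {self.scale_tag!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids),
            self.values[idx], self.scale_tag,
        )

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[j] for j in idx],
            self.values[:, idx], self.scale_tag,
        )

    def drop_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        drop = set(samples)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale_tag: str = "log2_tpm_plus1") -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float), scale_tag)


@dataclass
class QuantileReference:
    """Sorted reference distribution frozen from a training normalization."""

    sorted_reference: np.ndarray

    def __post_init__(self) -> None:
        self.sorted_reference = np.asarray(self.sorted_reference, dtype=float).ravel()
        if np.any(np.diff(self.sorted_reference) < 0):
            raise ExpressionError("quantile reference must be non-decreasing")

    def __len__(self) -> int:
        return self.sorted_reference.size


@dataclass
class PhenotypeTable:
    """Per-sample phenotype annotations.

    Columns: ``sample_id`` (required), and optionally ``condition``
    ({control, treated}), ``ki67_pre``/``ki67_post`` (percent stained cells,
    in [0, 100]), ``response`` ({responder, non_responder}) and ``group``
    (e.g. a risk class used for external-cohort comparisons).
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("sample_id", "condition", "ki67_pre", "ki67_post", "response", "group")

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns:
            raise ExpressionError("phenotype table requires a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ExpressionError("duplicate sample_id in phenotype table")
        for col in ("ki67_pre", "ki67_post"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                ok = vals.isna() | ((vals >= 0) & (vals <= 100))
                if not ok.all():
                    raise ExpressionError(f"{col} values must lie in [0, 100]")
                df[col] = vals
        if "condition" in df.columns:
            bad = set(df["condition"].dropna()) - {"control", "treated"}
            if bad:
                raise ExpressionError(f"unknown condition values: {sorted(bad)}")
        if "response" in df.columns:
            bad = set(df["response"].dropna()) - {"responder", "non_responder"}
            if bad:
                raise ExpressionError(f"unknown response values: {sorted(bad)}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def column(self, name: str, samples: Optional[Sequence[str]] = None) -> pd.Series:
        """Return one phenotype column indexed by sample id (optionally reordered)."""
        ser = self.table.set_index("sample_id")[name]
        if samples is not None:
            ser = ser.reindex([str(s) for s in samples])
        return ser

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        extra = set(self.sample_ids) - set(matrix.sample_ids)
        if extra:
            raise ExpressionError(f"phenotype samples not in matrix: {sorted(extra)[:10]}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, format: str = "tsv_matrix",
                           scale_tag: str = "log2_tpm_plus1") -> ExpressionMatrix:
    """Read a tab-delimited gene x sample matrix.

    The first column holds gene ids, the header row sample ids. Duplicate
    ids, non-numeric cells and missing values are rejected with an error
    naming the offending line.
    """
    if format != "tsv_matrix":
        raise ExpressionError(f"unsupported format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ExpressionError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ExpressionError(f"{path}: no data rows")
    if df.index.hasnans or any(str(g).strip() == "" for g in df.index):
        raise ExpressionError(f"{path}: empty gene id")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ExpressionError(f"{path}: duplicate gene ids {list(map(str, dup[:5]))}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            # +2: header row plus 1-based counting
            line = df.index.get_loc(bad[0]) + 2
            raise ExpressionError(
                f"{path}: non-numeric or missing value in column {col!r}, line {line}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                            values, scale_tag)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as tab-delimited text (gene ids in column 1)."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a phenotype CSV (columns sample_id, condition, ki67_pre, ...)."""
    return PhenotypeTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def aggregate_probes(matrix: ExpressionMatrix,
                     probe_map: Mapping[str, str],
                     replicate_map: Optional[Mapping[str, str]] = None) -> ExpressionMatrix:
    """Collapse probes to genes, then replicate samples to subjects.

    Probe values mapping to the same gene are arithmetically averaged first;
    replicate columns mapping to the same subject are averaged second (the
    order matters when probe counts differ between replicates). Probes absent
    from ``probe_map`` are dropped with a logged count.
    """
    if not probe_map:
        raise ExpressionError("probe_map is empty")
    probe_map = {str(k): str(v) for k, v in probe_map.items()}
    mapped = [p for p in matrix.gene_ids if p in probe_map]
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        logger.info("aggregate_probes: dropped %d unmapped probes", dropped)
    if not mapped:
        raise ExpressionError("no probes could be mapped to genes")

    df = matrix.to_dataframe().loc[mapped]
    genes = df.groupby([probe_map[p] for p in mapped], sort=False).mean()

    if replicate_map:
        replicate_map = {str(k): str(v) for k, v in replicate_map.items()}
        missing = [s for s in genes.columns if s not in replicate_map]
        if missing:
            raise ExpressionError(f"samples missing from replicate_map: {missing[:10]}")
        genes = genes.T.groupby([replicate_map[s] for s in genes.columns], sort=False).mean().T
    return ExpressionMatrix.from_dataframe(genes, matrix.scale_tag)


def filter_low_info(matrix: ExpressionMatrix, var_percentile: float = 25.0,
                    expr_percentile: float = 30.0) -> ExpressionMatrix:
    """Remove low-variance and low-expression genes.

    A gene is removed when its across-sample variance is at or below the
    ``var_percentile`` of all gene variances, OR its mean expression is at or
    below the ``expr_percentile`` of all gene means (union of the two rules;
    cutoffs by the linear-interpolation percentile convention, inclusive).
    Survivors keep their input order.
    """
    for name, p in (("var_percentile", var_percentile), ("expr_percentile", expr_percentile)):
        if not (0 <= p < 100):
            raise ExpressionError(f"{name} must lie in [0, 100), got {p}")
    variances = matrix.values.var(axis=1, ddof=1)
    means = matrix.values.mean(axis=1)
    var_cut = np.percentile(variances, var_percentile)
    expr_cut = np.percentile(means, expr_percentile)
    keep = (variances > var_cut) & (means > expr_cut)
    if not keep.any():
        raise ExpressionError("all genes filtered")
    logger.info("filter_low_info: kept %d of %d genes", int(keep.sum()), matrix.n_genes)
    return ExpressionMatrix(
        [g for g, k in zip(matrix.gene_ids, keep) if k], list(matrix.sample_ids),
        matrix.values[keep], matrix.scale_tag,
    )


def _map_to_reference(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a column's values by reference values at their within-column
    ranks; tied values receive the mean of the tied reference positions."""
    order = np.argsort(column, kind="stable")
    out = np.empty_like(column)
    sorted_vals = column[order]
    # walk runs of equal values and average the reference slots they occupy
    i = 0
    n = column.size
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        out[order[i:j + 1]] = reference[i:j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(matrix: ExpressionMatrix,
                       reference: Optional[QuantileReference] = None,
                       ) -> tuple[ExpressionMatrix, QuantileReference]:
    """Quantile-normalize columns, optionally onto a frozen reference.

    Without a reference, the reference distribution is the per-rank mean of
    the column-sorted values and every column is mapped onto it (so all
    columns end up with an identical value multiset). With a reference —
    typically frozen from a training normalization — each column is mapped
    onto the provided distribution instead, which is how held-out samples are
    projected without touching the training data.
    """
    if matrix.n_samples < 1:
        raise ExpressionError("need at least one sample")
    if reference is None:
        ref = np.sort(matrix.values, axis=0).mean(axis=1)
        reference = QuantileReference(ref)
    elif len(reference) != matrix.n_genes:
        raise ExpressionError(
            f"reference length {len(reference)} != gene count {matrix.n_genes}"
        )
    ref = reference.sorted_reference
    out = np.column_stack([_map_to_reference(matrix.values[:, j], ref)
                           for j in range(matrix.n_samples)])
    return (ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                             out, matrix.scale_tag), reference)


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to mean 0 and sample standard deviation 1 (ddof=1).

    Constant genes cannot be standardized and are dropped with a logged
    warning so downstream correlation and information computations never see
    zero-variance predictors.
    """
    if matrix.n_samples < 2:
        raise ExpressionError("standardization needs at least 2 samples")
    means = matrix.values.mean(axis=1, keepdims=True)
    sds = matrix.values.std(axis=1, ddof=1, keepdims=True)
    keep = sds.ravel() > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning("standardize_genes: dropped %d constant genes (e.g. %s)",
                       len(dropped), dropped[:5])
    if not keep.any():
        raise ExpressionError("all genes constant; nothing to standardize")
    values = (matrix.values[keep] - means[keep]) / sds[keep]
    return ExpressionMatrix([g for g, k in zip(matrix.gene_ids, keep) if k],
                            list(matrix.sample_ids), values, "standardized")
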