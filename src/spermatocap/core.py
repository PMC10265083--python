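"""Core data model, I/O, QC, normalization and shared statistics.

The central container is :class:`CellMatrix`, a gene x cell matrix of raw
UMI/read counts with per-cell metadata (donor, group, optionally a cell type)
and per-gene ribosomal/mitochondrial flags. Normalization follows the
3'-tag convention used throughout the package: per-cell tag counts are
rescaled to one million ("TPM" without any gene-length term, which is
meaningless for 3'-end counting protocols) and transformed to
``log2(TPM/10 + 1)``. Ribosomal and mitochondrial genes are excluded before
rescaling.

Two statistical primitives shared by every downstream module live here:
the two-sided Mann-Whitney-Wilcoxon rank-sum test and the Pearson chi-square
test on r x c contingency tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy import stats

logger = logging.getLogger(__name__)

RIBOSOMAL_RE = re.compile(r"^RP[SL]")
MITOCHONDRIAL_RE = re.compile(r"^MT-")

GENE_SET_ROLES = ("g1s", "g2m", "spermatogenesis", "apoptosis", "marker_panel", "custom")


class LoadError(ValueError):
    """Raised when an input file fails validation."""


@dataclass
class GeneSet:
    """A named list of gene symbols with a role tag."""

    name: str
    role: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in GENE_SET_ROLES:
            raise ValueError(f"unknown gene-set role {self.role!r}")
        genes = tuple(str(g).upper() for g in self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TestResult:
    """Result of a two-sample or contingency test."""

    statistic: float
    p_value: float
    effect: float | None = None
    n1: int = 0
    n2: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_symbols(symbols: np.ndarray) -> np.ndarray:
    symbols = np.asarray([str(s).upper() for s in symbols], dtype=object)
    if len(set(symbols)) != len(symbols):
        counts = pd.Series(symbols).value_counts()
        offenders = list(counts[counts > 1].index[:5])
        raise LoadError(f"duplicate gene symbols after upper-casing: {offenders}")
    return symbols


@dataclass
class CellMatrix:
    """Gene x cell raw counts with per-cell metadata and per-gene flags."""

    counts: scipy.sparse.csr_matrix
    gene_symbols: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        self.gene_symbols = _check_symbols(np.asarray(self.gene_symbols))
        self.cell_ids = np.asarray([str(c) for c in self.cell_ids], dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise LoadError("duplicate cell ids")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_symbols):
            raise LoadError(
                f"dimension mismatch: {n_genes} matrix rows vs "
                f"{len(self.gene_symbols)} gene symbols"
            )
        if n_cells != len(self.cell_ids):
            raise LoadError(
                f"dimension mismatch: {n_cells} matrix columns vs "
                f"{len(self.cell_ids)} cell ids"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise LoadError("negative counts")
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        if self.gene_flags is None:
            self.gene_flags = flag_genes(self.gene_symbols)
        else:
            self.gene_flags = self.gene_flags.reindex(self.gene_symbols)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(
            counts=self.counts[:, mask],
            gene_symbols=self.gene_symbols,
            cell_ids=self.cell_ids[mask],
            cell_meta=self.cell_meta.loc[self.cell_ids[mask]],
            gene_flags=self.gene_flags,
        )


def flag_genes(symbols: Sequence[str]) -> pd.DataFrame:
    """Flag ribosomal (``RPS*``/``RPL*``) and mitochondrial (``MT-*``) symbols.

    The matching is case-insensitive on the upper-cased symbol; the rule is a
    symbol-prefix convention, the standard proxy when no annotation is given.
    """
    symbols = [str(s).upper() for s in symbols]
    return pd.DataFrame(
        {
            "ribosomal": [bool(RIBOSOMAL_RE.match(s)) for s in symbols],
            "mitochondrial": [bool(MITOCHONDRIAL_RE.match(s)) for s in symbols],
        },
        index=pd.Index(symbols, name="gene"),
    )


@dataclass
class NormalizedMatrix:
    """Gene x cell values on the log2(TPM/10 + 1) scale.

    ``values`` is dense float64. ``excluded_genes`` lists symbols dropped
    before per-cell rescaling (ribosomal/mitochondrial by default).
    """

    values: np.ndarray
    gene_symbols: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    excluded_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_symbols), len(self.cell_ids)):
            raise ValueError("normalized matrix dimensions inconsistent")
        self._gene_index = pd.Index(self.gene_symbols)
        self._cell_index = pd.Index(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_positions(self, genes: Iterable[str]) -> np.ndarray:
        """Positions of the subset of ``genes`` present in the matrix."""
        idx = self._gene_index.get_indexer([g.upper() for g in genes])
        return idx[idx >= 0]

    def cell_positions(self, cells: Iterable[str] | None) -> np.ndarray:
        if cells is None:
            return np.arange(self.n_cells)
        idx = self._cell_index.get_indexer(list(cells))
        if (idx < 0).any():
            missing = np.asarray(list(cells))[idx < 0][:5]
            raise KeyError(f"unknown cell ids: {list(missing)}")
        return idx


# ---------------------------------------------------------------------------
# I/O


def _read_two_col_meta(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise LoadError(f"{path}: expected a 'cell_id' column, got {list(df.columns)}")
    return df.set_index("cell_id")


def load_counts(path: str | Path, format: str = "mtx") -> CellMatrix:
    """Load a counts matrix from an MTX fixture directory or a dense TSV.

    ``mtx`` expects ``matrix.mtx`` (genes x cells), ``genes.tsv`` (one symbol
    per line) and ``cells.tsv`` (TSV with ``cell_id``, ``donor``, ``group``
    and optionally ``cell_type``). ``tsv`` expects a dense table with gene
    symbols as the row index and cell ids as columns; a ``cells.tsv`` sidecar
    next to it is used for metadata when present.
    """
    path = Path(path)
    if format == "mtx":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise LoadError(f"missing {mtx}")
        counts = scipy.sparse.csr_matrix(scipy.io.mmread(mtx))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
        meta = _read_two_col_meta(path / "cells.tsv")
        cells = meta.index.to_numpy()
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = scipy.sparse.csr_matrix(df.to_numpy())
        genes = df.index.to_numpy()
        cells = df.columns.to_numpy()
        sidecar = path.parent / "cells.tsv"
        if sidecar.exists():
            meta = _read_two_col_meta(sidecar)
        else:
            meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    else:
        raise ValueError(f"unknown format {format!r}")
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise LoadError(f"{path}: non-integer counts")
    counts.data = np.round(counts.data)
    return CellMatrix(
        counts=counts.astype(np.int64),
        gene_symbols=genes,
        cell_ids=cells,
        cell_meta=meta,
    )


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(
    matrix: CellMatrix,
    min_genes: int = 2000,
    min_transcripts: int = 10000,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Retain cells with MORE THAN ``min_genes`` detected genes and MORE THAN
    ``min_transcripts`` total counts (strict inequalities on both).

    Returns the filtered matrix and a per-cell report with the detected-gene
    and transcript totals plus the removal reason for dropped cells.
    """
    if min_genes < 0 or min_transcripts < 0:
        raise ValueError("QC thresholds must be >= 0")
    csc = matrix.counts.tocsc()
    n_detected = np.diff(csc.indptr)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    keep = (n_detected > min_genes) & (totals > min_transcripts)
    reasons = []
    for d, t, k in zip(n_detected, totals, keep):
        if k:
            reasons.append("")
        else:
            bits = []
            if d <= min_genes:
                bits.append(f"genes<={min_genes}")
            if t <= min_transcripts:
                bits.append(f"transcripts<={min_transcripts}")
            reasons.append(",".join(bits))
    report = pd.DataFrame(
        {
            "n_genes": n_detected,
            "n_transcripts": totals.astype(np.int64),
            "retained": keep,
            "reason": reasons,
        },
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    return matrix.subset_cells(keep), report


def normalize(
    matrix: CellMatrix,
    exclude_flags: Sequence[str] = ("ribosomal", "mitochondrial"),
) -> NormalizedMatrix:
    """Compute log2(TPM/10 + 1) values after dropping flagged genes.

    TPM here is counts-per-million per cell with no gene-length term (3'-tag
    protocol). Excluded genes are removed *before* the per-cell rescaling, so
    the remaining genes sum to 1e6 TPM in every cell.
    """
    drop = np.zeros(matrix.n_genes, dtype=bool)
    for flag in exclude_flags:
        if flag not in matrix.gene_flags.columns:
            raise ValueError(f"unknown gene flag {flag!r}")
        drop |= matrix.gene_flags[flag].to_numpy()
    keep = ~drop
    if not keep.any():
        raise ValueError("no genes left after exclusion")
    counts = np.asarray(matrix.counts[keep, :].todense(), dtype=np.float64)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(matrix.cell_ids[totals == 0])
        raise ValueError(f"cells with zero counts after gene exclusion: {bad}")
    tpm = counts / totals * 1e6
    return NormalizedMatrix(
        values=np.log2(tpm / 10.0 + 1.0),
        gene_symbols=matrix.gene_symbols[keep],
        cell_ids=matrix.cell_ids,
        cell_meta=matrix.cell_meta,
        excluded_genes=tuple(matrix.gene_symbols[drop]),
    )


# ---------------------------------------------------------------------------
# Gene-set scoring


def gene_set_zscore(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    cells: Iterable[str] | np.ndarray | None = None,
) -> tuple[pd.Series, int]:
    """Average z-score of a gene set per cell, over a cell subset.

    Each set gene present in the matrix is z-scored across the subset
    (sample standard deviation, n-1); genes with zero variance are dropped
    with a logged warning. The score of a cell is the mean z over surviving
    set genes. Returns ``(scores, n_genes_used)``.
    """
    cell_idx = norm.cell_positions(None if cells is None else list(cells))
    if len(cell_idx) < 2:
        raise ValueError("gene_set_zscore needs at least 2 cells")
    gene_idx = norm.gene_positions(gene_set.genes)
    if len(gene_idx) == 0:
        raise ValueError(f"no genes of set {gene_set.name!r} present in matrix")
    sub = norm.values[np.ix_(gene_idx, cell_idx)]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    usable = sd.ravel() > 0
    if not usable.any():
        raise ValueError(
            f"all genes of set {gene_set.name!r} have zero variance over the subset"
        )
    if (~usable).any():
        dropped = norm.gene_symbols[gene_idx[~usable]]
        logger.warning(
            "gene_set_zscore(%s): dropped %d zero-variance genes: %s",
            gene_set.name, (~usable).sum(), list(dropped[:10]),
        )
    z = (sub[usable] - mean[usable]) / sd[usable]
    scores = pd.Series(
        z.mean(axis=0), index=pd.Index(norm.cell_ids[cell_idx], name="cell_id")
    )
    return scores, int(usable.sum())


# ---------------------------------------------------------------------------
# Shared tests


def wilcoxon_test(group1: Sequence[float], group2: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Uses the exact null distribution when ``n1 + n2 <= 12`` and the pooled
    sample has no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise. ``effect`` is ``mean(group1) -
    mean(group2)`` on whatever scale the inputs are on.
    """
    x = np.asarray(group1, dtype=np.float64)
    y = np.asarray(group2, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect=float(x.mean() - y.mean()),
        n1=int(x.size),
        n2=int(y.size),
    )


def chisq_test(table: np.ndarray | Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test on an r x c table, no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any():
        raise ValueError(f"zero row marginal at row {int(np.argmin(row_sums > 0))}")
    if (col_sums == 0).any():
        raise ValueError(f"zero column marginal at column {int(np.argmin(col_sums > 0))}")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        effect=None,
        n1=int(table.shape[0]),
        n2=int(table.shape[1]),
    )
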