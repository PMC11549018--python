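"""Core containers and I/O for paired single-cell expression / accessibility data.

The package operates on a gene x cell expression count matrix and a peak x cell
chromatin accessibility count matrix measured in the same cells (shared
barcodes), plus genomic coordinates: a TSS per gene and an interval per peak.
Candidate enhancers for a gene are the accessibility peaks whose interval
overlaps a window (default +/-500 kb) around the gene's TSS; the peak covering
the gene's promoter is tracked separately as the gene's promoter accessibility
and excluded from the candidate set.

Coordinates are BED-style 0-based half-open throughout; distances in base pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionMatrix",
    "AccessibilityMatrix",
    "CandidatePairs",
    "MultiomeData",
    "FormatError",
    "ValidationError",
    "read_matrix_market",
    "write_matrix_market",
    "read_dense_tsv",
    "read_bed",
    "read_gene_annotation",
    "align_cells",
    "log_normalized",
    "filter_genes",
    "enumerate_candidates",
]

_PEAK_RE = re.compile(r"^(\S+)[:_](\d+)[-_](\d+)$")


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


class ValidationError(ValueError):
    """Inputs that parse but violate a container invariant."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index[:5].tolist()
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionMatrix:
    """Gene x cell raw expression counts with gene identifiers and TSS records.

    ``tss`` maps gene_id -> (chrom, tss, strand); genes absent from it are
    treated as unmappable and dropped from candidate enumeration.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    tss: pd.DataFrame | None = None  # index gene_id, cols: chrom, tss, strand

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative expression counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if len(idx) == 0:
            raise KeyError(gene_id)
        return int(idx[0])

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx],
            gene_ids=self.gene_ids[idx],
        )

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(self, counts=self.counts[:, idx], cell_ids=self.cell_ids[idx])


@dataclass
class AccessibilityMatrix:
    """Peak x cell accessibility counts with peak intervals (0-based half-open)."""

    counts: sp.csr_matrix
    peaks: pd.DataFrame  # columns chrom, start, end; row order == matrix rows
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.peaks = self.peaks.reset_index(drop=True)
        if self.counts.shape != (len(self.peaks), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.peaks)} peaks, {len(self.cell_ids)} cells)"
            )
        _check_unique(self.cell_ids, "cell ids")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            bad = self.peaks.query("start >= end").index[:5].tolist()
            raise ValidationError(f"peaks with start >= end at rows {bad}")
        key = self.peaks[["chrom", "start", "end"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate peak coordinates")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative accessibility counts")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def peak_names(self) -> np.ndarray:
        p = self.peaks
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(p["chrom"], p["start"], p["end"])],
            dtype=object,
        )

    def binarized(self) -> sp.csr_matrix:
        """Peak x cell boolean matrix: count > 0 means the peak is accessible."""
        b = self.counts.copy()
        b.data = (b.data > 0).astype(np.int8)
        b.eliminate_zeros()
        return b

    def subset_cells(self, idx) -> "AccessibilityMatrix":
        idx = np.asarray(idx)
        return replace(self, counts=self.counts[:, idx], cell_ids=self.cell_ids[idx])


@dataclass
class CandidatePairs:
    """Per-gene candidate enhancer sets with TSS-to-peak-midpoint distances.

    ``table`` has one row per (gene_id, peak_index) candidate with the distance
    in bp; ``promoter_peak`` maps gene_id to the index of the peak overlapping
    the gene's promoter window (absent when no peak does).
    """

    table: pd.DataFrame  # columns: gene_id, peak_index, distance
    promoter_peak: dict = field(default_factory=dict)
    window: int = 500_000

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if len(t) and t.duplicated(["gene_id", "peak_index"]).any():
            raise ValidationError("duplicate (gene, peak) candidate records")
        if len(t) and (t["distance"] < 0).any():
            raise ValidationError("negative candidate distance")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def genes(self) -> np.ndarray:
        return self.table["gene_id"].unique()

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.table[self.table["gene_id"] == gene_id]

    def pair_labels(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.table[["gene_id", "peak_index"]])


@dataclass
class MultiomeData:
    """Aligned expression + accessibility matrices and the candidate pair set."""

    expr: ExpressionMatrix
    acc: AccessibilityMatrix
    pairs: CandidatePairs


# ---------------------------------------------------------------------------
# I/O


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_matrix_market(path_matrix, path_features, path_barcodes, kind=None):
    """Read a 10x-style MTX triplet into an expression or accessibility matrix.

    ``kind`` is "expression" or "accessibility"; when omitted it is inferred:
    features that all parse as ``chrom:start-end`` intervals are peaks,
    anything else is genes.
    """
    mat = sp.csr_matrix(mmread(path_matrix))
    features = [ln.split("\t")[0] for ln in _read_lines(path_features)]
    barcodes = [ln.split("\t")[0] for ln in _read_lines(path_barcodes)]
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix {mat.shape} inconsistent with {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    parsed = [_PEAK_RE.match(f) for f in features]
    if kind is None:
        kind = "accessibility" if features and all(parsed) else "expression"
    if kind == "accessibility":
        if not all(parsed):
            raise FormatError("accessibility features must be chrom:start-end")
        peaks = pd.DataFrame(
            [(m.group(1), int(m.group(2)), int(m.group(3))) for m in parsed],
            columns=["chrom", "start", "end"],
        )
        return AccessibilityMatrix(mat, peaks, np.array(barcodes, dtype=object))
    return ExpressionMatrix(mat, np.array(features, dtype=object), np.array(barcodes, dtype=object))


def write_matrix_market(matrix, path_matrix, path_features, path_barcodes) -> None:
    """Write an Expression/AccessibilityMatrix as an MTX triplet (lossless)."""
    mmwrite(str(path_matrix), sp.coo_matrix(matrix.counts))
    if isinstance(matrix, AccessibilityMatrix):
        features = matrix.peak_names()
    else:
        features = matrix.gene_ids
    with open(path_features, "w") as fh:
        fh.writelines(f"{f}\n" for f in features)
    with open(path_barcodes, "w") as fh:
        fh.writelines(f"{b}\n" for b in matrix.cell_ids)


def read_dense_tsv(path, kind="expression"):
    """Read a small dense TSV fixture (rows = features, columns = cells)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = sp.csr_matrix(df.to_numpy())
    cells = np.array(df.columns, dtype=object)
    if kind == "accessibility":
        parsed = [_PEAK_RE.match(str(f)) for f in df.index]
        if not all(parsed):
            raise FormatError("accessibility row names must be chrom:start-end")
        peaks = pd.DataFrame(
            [(m.group(1), int(m.group(2)), int(m.group(3))) for m in parsed],
            columns=["chrom", "start", "end"],
        )
        return AccessibilityMatrix(mat, peaks, cells)
    return ExpressionMatrix(mat, np.array(df.index, dtype=object), cells)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file of peak intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": int, "end": int})


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene annotation needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in annotation")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# Alignment / normalization


def align_cells(expr: ExpressionMatrix, acc: AccessibilityMatrix):
    """Restrict both modalities to their shared barcodes, in a common order.

    The order follows the expression matrix's barcode order restricted to the
    intersection, so jointly re-permuting both inputs leaves results unchanged.
    """
    shared = set(expr.cell_ids) & set(acc.cell_ids)
    if not shared:
        raise ValidationError("no shared cell barcodes between modalities")
    keep_e = [i for i, b in enumerate(expr.cell_ids) if b in shared]
    order = {b: i for i, b in enumerate(expr.cell_ids[keep_e])}
    keep_a = sorted(
        (i for i, b in enumerate(acc.cell_ids) if b in shared),
        key=lambda i: order[acc.cell_ids[i]],
    )
    expr2, acc2 = expr.subset_cells(keep_e), acc.subset_cells(keep_a)
    assert list(expr2.cell_ids) == list(acc2.cell_ids)
    return expr2, acc2


def log_normalized(expr: ExpressionMatrix) -> np.ndarray:
    """log1p of library-size normalized counts, scaled to the median depth.

    Returns a dense gene x cell float array. Cells with zero depth get zeros.
    """
    counts = np.asarray(expr.counts.todense(), dtype=float)
    depth = counts.sum(axis=0)
    target = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.divide(target, depth, out=np.zeros_like(depth), where=depth > 0)
    return np.log1p(counts * scale)


# ---------------------------------------------------------------------------
# Candidate enumeration and gene filtering


def enumerate_candidates(
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    window: int = 500_000,
    promoter_window: tuple[int, int] = (-2000, 200),
) -> CandidatePairs:
    """Enumerate candidate (gene, peak) pairs within ``window`` bp of each TSS.

    A peak is a candidate for a gene when its interval overlaps
    [TSS - window, TSS + window]. The distance is |TSS - floor((start+end)/2)|.
    Peaks overlapping the strand-aware promoter window are recorded as the
    gene's promoter peak (largest overlap wins) and excluded from the
    candidate set. Genes without a TSS record, or on a chromosome with no
    peaks, get zero candidates.
    """
    if expr.tss is None:
        raise ValidationError("expression matrix has no TSS annotation")
    starts = acc.peaks["start"].to_numpy()
    ends = acc.peaks["end"].to_numpy()
    mids = (starts + ends) // 2
    by_chrom = {c: np.flatnonzero((acc.peaks["chrom"] == c).to_numpy()) for c in acc.peaks["chrom"].unique()}

    lo_off, hi_off = promoter_window
    records = []
    promoter: dict[str, int] = {}
    for gene in expr.gene_ids:
        if gene not in expr.tss.index:
            continue
        rec = expr.tss.loc[gene]
        chrom, tss, strand = rec["chrom"], int(rec["tss"]), rec.get("strand", "+")
        idx = by_chrom.get(chrom)
        if idx is None or len(idx) == 0:
            continue
        s, e, m = starts[idx], ends[idx], mids[idx]
        in_window = (s <= tss + window) & (e > tss - window)
        # strand-aware promoter window around the TSS
        if strand == "-":
            p_lo, p_hi = tss - hi_off, tss - lo_off
        else:
            p_lo, p_hi = tss + lo_off, tss + hi_off
        overlap = np.minimum(e, p_hi) - np.maximum(s, p_lo)
        is_prom = overlap > 0
        if is_prom.any():
            best = np.flatnonzero(is_prom)[np.argmax(overlap[is_prom])]
            promoter[gene] = int(idx[best])
        for j in np.flatnonzero(in_window & ~is_prom):
            records.append((gene, int(idx[j]), int(abs(tss - m[j]))))
    table = pd.DataFrame(records, columns=["gene_id", "peak_index", "distance"])
    return CandidatePairs(table, promoter, window)


def filter_genes(
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    min_cell_frac: float = 0.05,
    top_variable: int = 8000,
    min_cis_peaks: int = 3,
    window: int = 500_000,
    variance_on: str = "log_normalized",
) -> ExpressionMatrix:
    """Retain genes expressed in >``min_cell_frac`` of cells, among the
    ``top_variable`` most variable, and with >= ``min_cis_peaks`` candidate
    peaks in the TSS window.

    The expression rule is strict (a gene detected in exactly 5% of cells is
    removed at the default threshold). Variance is computed on log1p
    library-size-normalized expression by default (``variance_on="raw"`` uses
    raw counts). Raises if no gene survives, with a per-rule attrition report.
    """
    n_cells = expr.n_cells
    detected = np.asarray((expr.counts > 0).sum(axis=1)).ravel()
    rule_expr = detected > min_cell_frac * n_cells

    if variance_on == "raw":
        values = np.asarray(expr.counts.todense(), dtype=float)
    else:
        values = log_normalized(expr)
    variances = values.var(axis=1)
    order = np.argsort(-variances, kind="stable")
    rule_var = np.zeros(expr.n_genes, dtype=bool)
    rule_var[order[:top_variable]] = True

    pairs = enumerate_candidates(expr, acc, window=window)
    counts = pairs.table.groupby("gene_id").size() if len(pairs) else pd.Series(dtype=int)
    n_cis = np.array([counts.get(g, 0) for g in expr.gene_ids])
    rule_cis = n_cis >= min_cis_peaks

    keep = rule_expr & rule_var & rule_cis
    if not keep.any():
        raise ValidationError(
            "no genes survive filtering: "
            f"expressed-in->{min_cell_frac:.0%}-cells kept {int(rule_expr.sum())}, "
            f"top-{top_variable}-variable kept {int(rule_var.sum())}, "
            f">={min_cis_peaks}-cis-peaks kept {int(rule_cis.sum())} "
            f"of {expr.n_genes} genes"
        )
    return expr.subset_genes(keep)
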