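"""Accuracy and reproducibility evaluation of pair score tables.

Gold-standard interaction sets (chromatin-conformation, CRISPRi, enhancer
atlases...) report detected interactions only and define no negatives. The
labeling rule here restricts negatives to enhancers the assay demonstrably
detected: a candidate (gene, peak) is *positive* when the peak overlaps a gold
enhancer recorded with that gene, *negative* when the peak overlaps some gold
enhancer but none of its gold records involve the candidate gene, and
*not classified* otherwise (those pairs are excluded from the metrics).
Accuracy is AUROC (rank statistic, tie-corrected) and AUPR (step-wise
precision-recall, non-interpolated). Reproducibility between two biological
replicates counts how many pairs rank in the top n of both replicates after
mapping replicate-2 scores onto replicate-1 pairs by enhancer overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_model import CandidatePairs

__all__ = [
    "read_gold_standard",
    "aggregate_gold",
    "label_pairs",
    "compute_auroc_aupr",
    "reproducibility_curve",
    "wilcoxon_true_vs_false",
]

POSITIVE, NEGATIVE, NOT_CLASSIFIED = "positive", "negative", "not_classified"


def read_gold_standard(path) -> pd.DataFrame:
    """Read a gold-standard TSV with columns chrom, start, end, gene_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"gold standard needs columns {sorted(required)}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("gold standard has intervals with start >= end")
    return df[["chrom", "start", "end", "gene_id"]]


def aggregate_gold(gold_standards: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of several gold standards: a pair validated by any file is a
    positive in the aggregate."""
    return pd.concat(gold_standards, ignore_index=True).drop_duplicates()


def label_pairs(pairs: CandidatePairs, peaks: pd.DataFrame, gold: pd.DataFrame) -> pd.Series:
    """Label every candidate pair positive / negative / not_classified.

    ``peaks`` carries the interval of each candidate peak (chrom, start, end;
    row order = peak_index). Overlap is any shared base between the candidate
    peak and a gold enhancer interval on the same chromosome; a peak
    overlapping several gold enhancers is positive if any of them targets the
    candidate gene.
    """
    labels = []
    gold_by_chrom = {c: g for c, g in gold.groupby("chrom")}
    for _, row in pairs.table.iterrows():
        p = peaks.iloc[int(row["peak_index"])]
        g = gold_by_chrom.get(p["chrom"])
        if g is None:
            labels.append(NOT_CLASSIFIED)
            continue
        hit = (g["start"].to_numpy() < p["end"]) & (g["end"].to_numpy() > p["start"])
        if not hit.any():
            labels.append(NOT_CLASSIFIED)
        elif (g.loc[hit, "gene_id"] == row["gene_id"]).any():
            labels.append(POSITIVE)
        else:
            labels.append(NEGATIVE)
    out = pd.Series(labels, index=pairs.table.index, name="label")
    if (out == POSITIVE).sum() == 0:
        warnings.warn("gold standard yields zero positive pairs; metrics undefined")
    return out


def compute_auroc_aupr(table: pd.DataFrame, labels: pd.Series) -> tuple[float, float]:
    """AUROC and AUPR of a score table against pair labels.

    Not-classified pairs are excluded. AUROC uses the rank (Mann-Whitney)
    statistic with tie correction; AUPR is the step-wise average precision.
    ``labels`` must be aligned with ``table`` rows (same index).
    """
    lab = labels.loc[table.index]
    use = lab != NOT_CLASSIFIED
    y = (lab[use] == POSITIVE).to_numpy()
    s = table.loc[use, "score"].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative pair")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def _order_key(table: pd.DataFrame, peaks: pd.DataFrame, scores: np.ndarray) -> np.ndarray:
    """Stable ranking order: score desc, then gene id, then peak start."""
    start = peaks["start"].to_numpy()[table["peak_index"].to_numpy(dtype=int)]
    return np.lexsort((start, table["gene_id"].to_numpy(), -scores))


def map_replicate_scores(
    table_rep2: pd.DataFrame,
    peaks_rep1: pd.DataFrame,
    peaks_rep2: pd.DataFrame,
    table_rep1: pd.DataFrame,
    agg: str = "max",
) -> pd.Series:
    """Map replicate-2 scores onto replicate-1 pairs by enhancer overlap.

    For a replicate-1 pair (g, e1), every replicate-2 pair (g, e2) whose peak
    overlaps e1 contributes its score; multiple contributions are aggregated
    by ``agg`` ("max" default, "mean" optional). One-to-many mapping is
    allowed: an e2 overlapping two e1 peaks maps to both. Pairs with no
    overlapping scored enhancer get NaN.
    """
    rep2_by_gene = {g: t for g, t in table_rep2.groupby("gene_id")}
    out = np.full(len(table_rep1), np.nan)
    aggfun = np.max if agg == "max" else np.mean
    for i, (_, row) in enumerate(table_rep1.iterrows()):
        t2 = rep2_by_gene.get(row["gene_id"])
        if t2 is None:
            continue
        p1 = peaks_rep1.iloc[int(row["peak_index"])]
        p2 = peaks_rep2.iloc[t2["peak_index"].to_numpy(dtype=int)]
        hit = (
            (p2["chrom"].to_numpy() == p1["chrom"])
            & (p2["start"].to_numpy() < p1["end"])
            & (p2["end"].to_numpy() > p1["start"])
        )
        if hit.any():
            out[i] = aggfun(t2["score"].to_numpy(dtype=float)[hit])
    return pd.Series(out, index=table_rep1.index, name="mapped_score")


def reproducibility_curve(
    table_rep1: pd.DataFrame,
    table_rep2: pd.DataFrame,
    peaks_rep1: pd.DataFrame,
    peaks_rep2: pd.DataFrame,
    n_grid,
    agg: str = "max",
) -> pd.DataFrame:
    """Overlap between the top-n pairs of two replicates, for each n.

    Replicate-2 scores are first mapped onto replicate-1 pairs by enhancer
    overlap; pairs with no mapped score or with an exactly-zero statistic in
    either replicate are excluded. overlap(n) <= n always, with equality for
    identical replicates.
    """
    mapped = map_replicate_scores(table_rep2, peaks_rep1, peaks_rep2, table_rep1, agg)
    s1 = table_rep1["score"].to_numpy(dtype=float)
    s2 = mapped.to_numpy()
    keep = ~np.isnan(s2) & (s1 != 0) & (s2 != 0)
    if not keep.any():
        warnings.warn("no overlapping enhancers between replicates; zero curve")
        return pd.DataFrame({"n": list(n_grid), "overlap": 0})
    sub = table_rep1.loc[keep].reset_index(drop=True)
    o1 = _order_key(sub, peaks_rep1, s1[keep])
    o2 = _order_key(sub, peaks_rep1, s2[keep])
    rows = []
    for n in n_grid:
        top1 = set(o1[:n])
        top2 = set(o2[:n])
        rows.append((int(n), len(top1 & top2)))
    return pd.DataFrame(rows, columns=["n", "overlap"])


def wilcoxon_true_vs_false(table: pd.DataFrame, labels: pd.Series) -> float:
    """One-sided rank-sum p-value that positive pairs score higher than
    negatives (exact for small groups)."""
    lab = labels.loc[table.index]
    pos = table.loc[lab == POSITIVE, "score"].to_numpy(dtype=float)
    neg = table.loc[lab == NEGATIVE, "score"].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both labeled groups must be non-empty")
    method = "exact" if max(len(pos), len(neg)) <= 20 else "asymptotic"
    return float(mannwhitneyu(pos, neg, alternative="greater", method=method).pvalue)
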