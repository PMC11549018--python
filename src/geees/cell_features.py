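"""Cell-level downstream products of the per-cell association scores.

The cells x pairs score matrix is itself a cell representation: restricting it
to the strongest pairs and masking entries where the gene is not expressed or
the enhancer is not accessible yields sparse features suitable for clustering
cells by their regulatory activity. Given a cluster assignment, per-cluster
interaction strengths are the within-cluster medians of the per-cell
statistic, normalized per gene by the maximum over that gene's enhancers and
all clusters, so the strongest (enhancer, cluster) combination of each gene
scores 1 and cluster contrasts are comparable across genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellPairScores
from .data_model import AccessibilityMatrix, ExpressionMatrix

__all__ = ["select_top_pairs", "masked_feature_matrix", "normalized_strengths"]


def select_top_pairs(table: pd.DataFrame, q: float = 0.001) -> pd.DataFrame:
    """The ceil(q * P) highest-scoring pairs of a score table.

    Ties are broken deterministically by (score desc, gene id, peak index).
    """
    if not 0 < q <= 1:
        raise ValueError(f"quantile q={q} outside (0, 1]")
    if table.empty:
        raise ValueError("empty score table")
    n = math.ceil(q * len(table))
    order = np.lexsort(
        (
            table["peak_index"].to_numpy(),
            table["gene_id"].to_numpy(),
            -table["score"].to_numpy(dtype=float),
        )
    )
    return table.iloc[order[:n]]


def masked_feature_matrix(
    cell_scores: CellPairScores,
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pair_subset: pd.DataFrame,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Cells x selected-pairs feature matrix with expression/accessibility
    masking.

    Entry (c, ge) is the per-cell score when cell c both expresses gene g
    (raw count > 0) and is accessible at enhancer e (raw count > 0), and 0
    otherwise. Returns the sparse matrix and the pair frame describing its
    columns.
    """
    key = pd.MultiIndex.from_frame(cell_scores.pairs[["gene_id", "peak_index"]])
    want = pd.MultiIndex.from_frame(pair_subset[["gene_id", "peak_index"]])
    col_of = {k: i for i, k in enumerate(key)}
    missing = [k for k in want if k not in col_of]
    if missing:
        raise KeyError(f"pairs not present in the scored set: {missing[:3]}")
    cols = np.array([col_of[k] for k in want])
    values = cell_scores.values[:, cols].copy()
    genes = [expr.gene_index(g) for g in pair_subset["gene_id"]]
    expressed = np.asarray((expr.counts[genes] > 0).todense()).T  # C x n
    accessible = np.asarray(
        (acc.counts[pair_subset["peak_index"].to_numpy(dtype=int)] > 0).todense()
    ).T
    values[~(expressed & accessible)] = 0.0
    out_pairs = pair_subset[["gene_id", "peak_index"]].reset_index(drop=True)
    return sp.csr_matrix(values), out_pairs


def normalized_strengths(
    cell_scores: CellPairScores,
    clusters,
    contrast: tuple | None = None,
) -> pd.DataFrame:
    """Per-cluster median interaction strengths, normalized within each gene.

    For pair (g, e) and cluster i, the strength is the median of the per-cell
    statistic over cluster-i cells; the normalized value divides by the
    maximum strength over the gene's enhancers and all clusters (all-zero
    genes stay 0 and are flagged). The returned frame has one row per
    (gene, peak, cluster) with columns strength, norm, and delta = the
    normalized difference between the two ``contrast`` clusters (default: the
    two first clusters in sorted label order).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != cell_scores.n_cells:
        raise ValueError("cluster assignment length != number of cells")
    labels = np.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    if any((clusters == lab).sum() == 0 for lab in labels):
        raise ValueError("empty cluster")
    if contrast is None:
        contrast = (labels[0], labels[1])

    med = {lab: np.median(cell_scores.values[clusters == lab], axis=0) for lab in labels}
    pairs = cell_scores.pairs
    rows = []
    for gene, sub in pairs.groupby("gene_id", sort=False):
        idx = sub.index.to_numpy()
        gene_max = max(float(med[lab][idx].max()) for lab in labels)
        for lab in labels:
            strengths = med[lab][idx]
            norm = strengths / gene_max if gene_max > 0 else np.zeros_like(strengths)
            for j, pk, s, nv in zip(idx, sub["peak_index"], strengths, norm):
                rows.append((gene, int(pk), lab, float(s), float(nv), gene_max == 0))
    out = pd.DataFrame(
        rows, columns=["gene_id", "peak_index", "cluster", "strength", "norm", "all_zero"]
    )
    c0, c1 = contrast
    n0 = out[out["cluster"] == c0].set_index(["gene_id", "peak_index"])["norm"]
    n1 = out[out["cluster"] == c1].set_index(["gene_id", "peak_index"])["norm"]
    delta = (n1 - n0).rename("delta")
    key = pd.MultiIndex.from_frame(out[["gene_id", "peak_index"]])
    out["delta"] = delta.loc[key].to_numpy()
    return out
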