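"""The cell-specific gene-enhancer association statistic.

For a gene g and candidate enhancer e, each cell c is scored by asking whether
the enhancer is unusually accessible among the k cells whose expression of g is
most similar to cell c's (the cell's expression neighborhood). Writing N_cge
for the number of neighborhood cells accessible at e and pi_e for the fraction
of all cells accessible at e, the null model is N_cge ~ Binomial(k, pi_e); the
per-cell score is -log10 of the exact upper-tail p-value, and the aggregate
pair score is the median of the per-cell scores:

    s_ge = median_c ( -log10 p_cge )

Large s_ge means the enhancer's accessibility is enriched in expression
neighborhoods across many cells, i.e. accessibility tracks expression at the
single-cell level (including non-linearly; the neighborhood construction makes
no linearity assumption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .data_model import (
    AccessibilityMatrix,
    CandidatePairs,
    ExpressionMatrix,
    MultiomeData,
    log_normalized,
)

__all__ = [
    "P_FLOOR",
    "Neighborhood",
    "CellPairScores",
    "build_neighborhood",
    "accessibility_fraction",
    "binomial_cell_test",
    "score_pair",
    "aggregate_scores",
    "run_geees",
    "GEEES",
]

# p-values are floored before log10 so scores stay finite
P_FLOOR = 1e-300


@dataclass
class Neighborhood:
    """The k cells whose expression of one gene is closest to a focal cell's."""

    focal_cell: int
    gene_id: str
    member_cells: np.ndarray  # length k, includes the focal cell


@dataclass
class CellPairScores:
    """Cells x candidate-pairs matrix of per-cell scores (-log10 p)."""

    values: np.ndarray  # shape (C, P), finite, >= 0
    cell_ids: np.ndarray
    pairs: pd.DataFrame  # columns gene_id, peak_index; row i == column i

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("cell-pair scores must be finite and non-negative")
        if self.values.shape != (len(self.cell_ids), len(self.pairs)):
            raise ValueError("cell-pair score shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


def _expression_values(expr: ExpressionMatrix, mode: str) -> np.ndarray:
    if mode == "raw":
        return np.asarray(expr.counts.todense(), dtype=float)
    if mode == "log_normalized":
        return log_normalized(expr)
    raise ValueError(f"unknown expression value mode {mode!r}")


def _neighbor_matrix(y: np.ndarray, k: int) -> np.ndarray:
    """Boolean C x C membership matrix: row c marks the k cells with expression
    closest to y[c]. Ties broken by ascending cell index (stable sort); the
    focal cell is always a member (distance 0, lowest possible)."""
    C = len(y)
    if k > C:
        raise ValueError(f"neighborhood size k={k} exceeds C={C} cells")
    dist = np.abs(y[None, :] - y[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    member = np.zeros((C, C), dtype=bool)
    member[np.arange(C)[:, None], nearest] = True
    return member


def build_neighborhood(
    expr: ExpressionMatrix,
    gene: str,
    cell: int,
    k: int = 30,
    expression_values: str = "log_normalized",
) -> Neighborhood:
    """The k cells (focal included) with expression of ``gene`` closest to the
    focal cell's, ties broken by ascending cell index."""
    if k > expr.n_cells:
        raise ValueError(f"k={k} must be <= number of cells ({expr.n_cells})")
    y = _expression_values(expr, expression_values)[expr.gene_index(gene)]
    dist = np.abs(y - y[cell])
    members = np.argsort(dist, kind="stable")[:k]
    return Neighborhood(cell, gene, np.sort(members))


def accessibility_fraction(acc: AccessibilityMatrix, peak: int) -> float:
    """Fraction of all cells in which ``peak`` is accessible (count > 0)."""
    row = acc.counts.getrow(peak)
    return float((row.data > 0).sum()) / acc.n_cells


def binomial_cell_test(
    N_cge: int, n_cg: int, pi_e: float, alternative: str = "two-sided"
) -> float:
    """Exact Binomial tail p-value for the neighborhood accessibility count.

    The default ``"two-sided"`` tests departure from the cell-wide
    accessibility in either direction (twice the smaller exact tail, capped at
    1): in a cell whose expression neighborhood is depleted of accessible
    cells the pair is just as clearly coupled as in an enriched one.
    ``alternative="greater"`` restricts to enrichment: p = P(X >= N) with
    X ~ Binomial(n, pi).
    Degenerate pi in {0, 1} returns 1 when the observation is the forced
    outcome.
    """
    if not 0 <= N_cge <= n_cg:
        raise ValueError(f"count N={N_cge} outside [0, n={n_cg}]")
    if not 0.0 <= pi_e <= 1.0:
        raise ValueError(f"pi={pi_e} outside [0, 1]")
    upper = float(binom.sf(N_cge - 1, n_cg, pi_e))
    if alternative == "greater":
        return upper
    if alternative == "two-sided":
        lower = float(binom.cdf(N_cge, n_cg, pi_e))
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


def _pvalue_matrix(N: np.ndarray, k: int, pi: np.ndarray, alternative: str) -> np.ndarray:
    upper = binom.sf(N - 1, k, pi)
    if alternative == "greater":
        return upper
    lower = binom.cdf(N, k, pi)
    return np.minimum(1.0, 2.0 * np.minimum(upper, lower))


def score_pair(
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    gene: str,
    peak: int,
    k: int = 30,
    alternative: str = "two-sided",
    expression_values: str = "log_normalized",
) -> np.ndarray:
    """Per-cell p-values for one candidate (gene, peak) pair."""
    sub = pairs.for_gene(gene)
    if peak not in set(sub["peak_index"]):
        raise KeyError(f"({gene}, peak {peak}) is not a candidate pair")
    y = _expression_values(expr, expression_values)[expr.gene_index(gene)]
    member = _neighbor_matrix(y, k)
    a = np.asarray(acc.binarized().getrow(peak).todense(), dtype=float).ravel()
    N = member @ a
    pi = a.mean()
    return _pvalue_matrix(N, k, np.full_like(N, pi), alternative)


def aggregate_scores(cell_scores: CellPairScores, method: str = "median") -> pd.DataFrame:
    """Aggregate per-cell scores into one association score per pair.

    The default (and standard) aggregation is the median over cells of the
    per-cell -log10 p; an even cell count uses the midpoint mean.
    """
    if cell_scores.n_cells == 0:
        raise ValueError("no cells to aggregate over")
    if method == "median":
        s = np.median(cell_scores.values, axis=0)
    elif method == "mean":
        s = cell_scores.values.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation {method!r}")
    out = cell_scores.pairs.copy()
    out["score"] = s
    out["method"] = "geees"
    return out


def run_geees(
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    k: int = 30,
    alternative: str = "two-sided",
    expression_values: str = "log_normalized",
    aggregate: str = "median",
) -> tuple[CellPairScores, pd.DataFrame]:
    """Score every candidate pair in every cell and aggregate.

    Neighborhoods are built once per gene (a C x C membership matrix) and
    reused across that gene's candidate enhancers.
    """
    if list(expr.cell_ids) != list(acc.cell_ids):
        raise ValueError("modalities are not cell-aligned; call align_cells first")
    C = expr.n_cells
    if k > C:
        raise ValueError(f"k={k} exceeds C={C}")
    Y = _expression_values(expr, expression_values)
    A = np.asarray(acc.binarized().todense(), dtype=float)
    pi_all = A.mean(axis=1)

    blocks = []
    tables = []
    for gene, sub in pairs.table.groupby("gene_id", sort=False):
        member = _neighbor_matrix(Y[expr.gene_index(gene)], k)
        peaks = sub["peak_index"].to_numpy()
        N = member.astype(float) @ A[peaks].T  # C x E_g
        p = _pvalue_matrix(N, k, pi_all[peaks][None, :], alternative)
        blocks.append(-np.log10(np.maximum(p, P_FLOOR)))
        tables.append(sub[["gene_id", "peak_index"]])
    if not blocks:
        raise ValueError("empty candidate pair set")
    pair_index = pd.concat(tables, ignore_index=True)
    cell_scores = CellPairScores(np.hstack(blocks), expr.cell_ids, pair_index)
    return cell_scores, aggregate_scores(cell_scores, aggregate)


class GEEES(BaseEstimator):
    """Estimator interface to the cell-specific association score.

    Parameters
    ----------
    k : int
        Expression-neighborhood size (the Binomial sample size n_cg).
    alternative : {"two-sided", "greater"}
        Sidedness of the Binomial test; the default treats neighborhood
        depletion of accessibility as evidence of coupling too.
    expression_values : {"log_normalized", "raw"}
        Expression scale on which neighborhoods are built.
    aggregate : {"median", "mean"}
        Aggregation of per-cell -log10 p into the pair score.

    Attributes
    ----------
    cell_scores_ : CellPairScores
        Cells x pairs matrix of -log10 p.
    pair_scores_ : pandas.DataFrame
        Columns gene_id, peak_index, score, method.
    """

    def __init__(self, k=30, alternative="two-sided", expression_values="log_normalized", aggregate="median"):
        self.k = k
        self.alternative = alternative
        self.expression_values = expression_values
        self.aggregate = aggregate

    def fit(self, data: MultiomeData, y=None):
        self.cell_scores_, self.pair_scores_ = run_geees(
            data.expr,
            data.acc,
            data.pairs,
            k=self.k,
            alternative=self.alternative,
            expression_values=self.expression_values,
            aggregate=self.aggregate,
        )
        return self
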