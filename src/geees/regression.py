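"""Sparse multivariate regression scoring of candidate enhancers.

Enhancer selection for a gene g is cast as variable selection: regress the
gene's expression (and, in some variants, its promoter accessibility) on the
accessibility of all candidate enhancers and score each enhancer by how often
it is selected. Three formulations:

* adaptive — weighted lasso ``(1/C)||y - b0 - X beta||^2 + lam * sum_e
  phi_ge |beta_ge|`` whose per-enhancer weights phi_ge are inversely
  proportional to the promoter/enhancer co-accessibility score, so enhancers
  co-accessible with the gene's promoter are penalized less;
* sequential — a first lasso of promoter accessibility on the enhancers acts
  as a screening step; only enhancers with strictly positive stage-1
  coefficients enter a second lasso of expression on the survivors;
* multi_response — expression and promoter accessibility are regressed jointly
  with a sparse-group penalty, each group being the coefficient pair
  (beta_ge, alpha_ge) of one enhancer, so an enhancer is selected or dropped
  for both responses together.

All three run under stability selection: the model is refit on ``n_subsamples``
random half-size subsamples over a wide (data-derived) regularization grid,
and an enhancer's score is the fraction of subsamples in which it is selected
at any *admissible* grid point — one whose fit keeps at most q = ceil(sqrt(0.8 E))
enhancers active (overridable), the per-fit sparsity bound under which
stability selection controls false selections; without it, the low end of a
wide grid selects everything and every frequency saturates at 1. The weighted lasso is solved exactly as a plain lasso after
rescaling predictor e by 1/phi_ge and back-transforming the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .data_model import AccessibilityMatrix, CandidatePairs, ExpressionMatrix, MultiomeData

__all__ = [
    "RegressionSpec",
    "compute_adaptive_weights",
    "fit_adaptive",
    "fit_sequential",
    "fit_multi_response",
    "stability_select",
    "lasso_kkt_violation",
    "StabilitySelection",
]


@dataclass
class RegressionSpec:
    """Stability-selection protocol parameters.

    The regularization grid is ``n_lambdas`` log-spaced values from the
    data-derived lambda_max (smallest penalty giving the null model) down to
    ``lambda_min_ratio * lambda_max``. ``sgl_alpha`` splits the multi-response
    penalty between the elementwise l1 part (alpha) and the group-norm part
    (1 - alpha).
    """

    variant: str = "adaptive"
    n_subsamples: int = 100
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.01
    sgl_alpha: float = 0.5
    weight_floor: float = 1e-3
    max_active: int | None = None  # per-fit sparsity bound; None = ceil(sqrt(0.8 E))
    seed: int = 0

    def active_bound(self, n_features: int) -> int:
        if self.max_active is not None:
            return self.max_active
        return max(1, int(np.ceil(np.sqrt(0.8 * n_features))))

    def __post_init__(self) -> None:
        if self.n_subsamples < 2:
            raise ValueError("need at least 2 subsamples")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


# ---------------------------------------------------------------------------
# design matrices and helpers


def _dense_row(mat, i: int) -> np.ndarray:
    return np.asarray(mat.getrow(i).todense(), dtype=float).ravel()


def gene_design(expr: ExpressionMatrix, acc: AccessibilityMatrix, pairs: CandidatePairs, gene: str):
    """(X, y, a_prom, peak_indices) for one gene: candidate accessibility as
    predictors, expression as response, promoter accessibility if available."""
    sub = pairs.for_gene(gene)
    if sub.empty:
        raise KeyError(f"gene {gene!r} has no candidate enhancers")
    peaks = sub["peak_index"].to_numpy()
    X = np.asarray(acc.counts[peaks].todense(), dtype=float).T
    y = _dense_row(expr.counts, expr.gene_index(gene))
    prom = pairs.promoter_peak.get(gene)
    a = _dense_row(acc.counts, prom) if prom is not None else None
    return X, y, a, peaks


def _standardize(M: np.ndarray) -> np.ndarray:
    """Center and scale to unit variance; zero-variance columns become zero."""
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    return np.divide(M, sd, out=np.zeros_like(M), where=sd > 0)


def lasso_kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float, weights=None) -> float:
    """Max violation of the weighted-lasso stationarity conditions.

    For objective (1/C)||y - b0 - X beta||^2 + lam * sum w_j |beta_j| with the
    intercept at its optimum, the subgradient conditions are
    |g_j| <= lam*w_j where beta_j = 0 and g_j = -lam*w_j*sign(beta_j)
    otherwise, with g_j = -(2/C) x_j^T r on centered data.
    """
    C = len(y)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    Xc = X - X.mean(axis=0)
    r = (y - y.mean()) - Xc @ beta
    g = -(2.0 / C) * Xc.T @ r
    active = beta != 0
    v_active = np.abs(g[active] + lam * w[active] * np.sign(beta[active]))
    v_zero = np.maximum(np.abs(g[~active]) - lam * w[~active], 0.0)
    parts = np.concatenate([v_active, v_zero])
    return float(parts.max()) if len(parts) else 0.0


def _lasso(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-12) -> np.ndarray:
    """Lasso coefficients for (1/C)RSS + lam*||beta||_1 (intercept fitted)."""
    if lam <= 0:
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        return beta
    model = Lasso(alpha=lam / 2.0, fit_intercept=True, max_iter=100_000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_.copy()


def lambda_max_lasso(X: np.ndarray, y: np.ndarray, weights=None) -> float:
    """Smallest lam at which the (weighted) lasso returns the null model."""
    Xc = X - X.mean(axis=0)
    grad = (2.0 / len(y)) * np.abs(Xc.T @ (y - y.mean()))
    if weights is not None:
        grad = grad / np.asarray(weights, dtype=float)
    return float(grad.max()) if len(grad) else 0.0


def _lambda_grid(lam_max: float, spec: RegressionSpec) -> np.ndarray:
    if lam_max <= 0:
        lam_max = 1e-8
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * spec.lambda_min_ratio), spec.n_lambdas
    )


# ---------------------------------------------------------------------------
# adaptive weights


def compute_adaptive_weights(
    coaccess: pd.DataFrame | None,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    floor: float = 1e-3,
) -> pd.Series:
    """Per-pair adaptive penalty weights phi_ge = 1 / max(co-accessibility, floor).

    ``coaccess`` is a table with columns gene_id, peak_index, score; pairs
    missing from it, or with non-positive scores, get the maximal weight
    1/floor. Without a table, a fallback co-accessibility is computed as
    max(0, Spearman correlation) between the gene's promoter-peak
    accessibility and the enhancer's accessibility; genes lacking a promoter
    peak fall back to the maximal weight.
    """
    t = pairs.table
    scores = np.full(len(t), np.nan)
    if coaccess is not None:
        lut = coaccess.set_index(["gene_id", "peak_index"])["score"]
        key = pd.MultiIndex.from_frame(t[["gene_id", "peak_index"]])
        present = key.isin(lut.index)
        scores[present] = lut.loc[key[present]].to_numpy(dtype=float)
    else:
        for gene, sub in t.groupby("gene_id", sort=False):
            prom = pairs.promoter_peak.get(gene)
            if prom is None:
                continue
            ap = _dense_row(acc.counts, prom)
            if np.ptp(ap) == 0:
                continue
            for row, peak in zip(sub.index, sub["peak_index"]):
                ae = _dense_row(acc.counts, int(peak))
                if np.ptp(ae) == 0:
                    continue
                scores[row] = spearmanr(ap, ae).statistic
    scores = np.where(np.isnan(scores) | (scores <= 0), floor, np.maximum(scores, floor))
    phi = 1.0 / scores
    return pd.Series(phi, index=pd.MultiIndex.from_frame(t[["gene_id", "peak_index"]]), name="phi")


# ---------------------------------------------------------------------------
# single fits


def fit_adaptive(
    gene: str,
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    weights: pd.Series,
    lam: float,
) -> np.ndarray:
    """Weighted-lasso coefficients for one gene at one penalty level.

    Solved exactly by rescaling predictor e by 1/phi_ge, fitting a plain
    lasso, and dividing the coefficients back.
    """
    X, y, _, peaks = gene_design(expr, acc, pairs, gene)
    phi = weights.loc[[(gene, int(p)) for p in peaks]].to_numpy(dtype=float)
    beta_scaled = _lasso(X / phi[None, :], y, lam)
    return beta_scaled / phi


def fit_sequential(
    gene: str,
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    lambda1: float,
    lambda2: float,
):
    """Two-stage lasso: screen enhancers on promoter accessibility, then
    regress expression on the screened set.

    Stage 1 regresses the gene's promoter accessibility on all candidate
    enhancers; only strictly positive coefficients survive. Stage 2 is a
    lasso of expression on the survivors; eliminated enhancers get
    coefficient 0. Returns (coefficients, survivor mask).
    """
    X, y, a, _ = gene_design(expr, acc, pairs, gene)
    if a is None:
        raise KeyError(f"gene {gene!r} has no promoter peak")
    stage1 = _lasso(X, a, lambda1)
    surv = stage1 > 0
    beta = np.zeros(X.shape[1])
    if surv.any():
        beta[surv] = _lasso(X[:, surv], y, lambda2)
    return beta, surv


def _sgl_solve(
    Xc: np.ndarray,
    Yc: np.ndarray,
    lam1: float,
    lam2: float,
    B0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
):
    """Block coordinate descent for the two-response sparse-group problem.

    Minimizes, over B (E x 2 with columns beta, alpha) on centered data,
        sum_r (1/(2C)) ||Yc[:, r] - Xc B[:, r]||^2
        + lam1 * sum |B| + lam2 * sum_e ||B[e, :]||_2.
    Groups are the per-enhancer coefficient pairs; the group update is the
    standard two-level soft-threshold (elementwise at lam1, then group
    shrinkage at lam2). Returns (B, converged).
    """
    C, E = Xc.shape
    c = (Xc * Xc).sum(axis=0) / C  # per-predictor curvature
    B = np.zeros((E, 2)) if B0 is None else B0.copy()
    R = Yc - Xc @ B  # residual matrix C x 2
    order = np.arange(E)
    for _ in range(max_iter):
        delta = 0.0
        for e in order:
            if c[e] == 0:
                continue
            old = B[e].copy()
            z = Xc[:, e] @ R / C + c[e] * old
            w = np.sign(z) * np.maximum(np.abs(z) - lam1, 0.0)
            nw = np.linalg.norm(w)
            new = np.zeros(2) if nw <= lam2 else (1.0 - lam2 / nw) * w / c[e]
            if not np.array_equal(new, old):
                R += np.outer(Xc[:, e], old - new)
                delta = max(delta, float(np.max(np.abs(new - old))))
                B[e] = new
        if delta < tol:
            return B, True
    return B, False


def fit_multi_response(
    gene: str,
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    pairs: CandidatePairs,
    lambda1: float,
    lambda2: float,
):
    """Joint sparse-group fit of expression and promoter accessibility.

    Returns (beta, alpha): beta links enhancer accessibility to expression,
    alpha to promoter accessibility; the group penalty zeroes or keeps each
    (beta_ge, alpha_ge) pair together.
    """
    X, y, a, _ = gene_design(expr, acc, pairs, gene)
    if a is None:
        raise KeyError(f"gene {gene!r} has no promoter peak")
    Xc = X - X.mean(axis=0)
    Yc = np.column_stack([y - y.mean(), a - a.mean()])
    B, converged = _sgl_solve(Xc, Yc, lambda1, lambda2)
    if not converged:
        warnings.warn(f"sparse-group solver did not converge for gene {gene}")
    return B[:, 0], B[:, 1]


def sgl_lambda_max(Xc: np.ndarray, Yc: np.ndarray, alpha: float) -> float:
    """Smallest lam at which every group is zero for the penalty split
    lam1 = alpha*lam, lam2 = (1-alpha)*lam."""
    C = Xc.shape[0]
    Z = Xc.T @ Yc / C  # E x 2 null-model gradients
    lam_max = 0.0
    for z in Z:
        hi = np.abs(z).max() / max(alpha, 1e-12) if alpha > 0 else np.linalg.norm(z) / max(1 - alpha, 1e-12)
        if hi <= 0:
            continue
        lo = 0.0
        for _ in range(60):
            mid = (lo + hi) / 2
            w = np.maximum(np.abs(z) - alpha * mid, 0.0)
            if np.linalg.norm(w) > (1 - alpha) * mid:
                lo = mid
            else:
                hi = mid
        lam_max = max(lam_max, hi)
    return lam_max


# ---------------------------------------------------------------------------
# stability selection


def stability_select(fit_fn, n_cells: int, n_features: int, spec: RegressionSpec) -> np.ndarray:
    """Empirical selection frequencies over seeded half-size subsamples.

    ``fit_fn(cell_idx)`` fits one subsample across the whole regularization
    grid and returns a boolean mask of enhancers selected at any grid point
    (max-over-lambda), or None for a failed fit (excluded from the
    denominator). Frequencies lie in [0, 1] and are reproducible for a fixed
    spec.seed.
    """
    if n_cells < 4:
        raise ValueError("stability selection needs at least 4 cells")
    rng = np.random.default_rng(spec.seed)
    half = n_cells // 2
    counts = np.zeros(n_features)
    valid = 0
    for _ in range(spec.n_subsamples):
        idx = np.sort(rng.choice(n_cells, size=half, replace=False))
        sel = fit_fn(idx)
        if sel is None:
            continue
        counts += np.asarray(sel, dtype=float)
        valid += 1
    if valid == 0:
        raise RuntimeError("all stability-selection fits failed")
    return counts / valid


def _admissible_any(active: np.ndarray, q: int) -> np.ndarray:
    """OR of per-grid-point selection masks over grid points with <= q active.

    ``active`` is (n_features, n_grid) boolean."""
    ok = active.sum(axis=0) <= q
    return active[:, ok].any(axis=1) if ok.any() else np.zeros(active.shape[0], dtype=bool)


def _path_select_adaptive(X, y, phi, grid, q):
    def sel(idx):
        # standardize first: rescaling by 1/phi afterwards is what turns the
        # plain lasso into the weighted one (the reverse order is a no-op)
        Xs = _standardize(X[idx]) / phi[None, :]
        ys = _standardize(y[idx, None])[:, 0]
        _, coefs, _ = lasso_path(Xs, ys, alphas=grid / 2.0)
        return _admissible_any(np.abs(coefs) > 0, q)

    return sel


def _path_select_sequential(X, y, a, grid1, grid2, q):
    def sel(idx):
        Xs = _standardize(X[idx])
        ys = _standardize(y[idx, None])[:, 0]
        as_ = _standardize(a[idx, None])[:, 0]
        _, c1, _ = lasso_path(Xs, as_, alphas=grid1 / 2.0)
        selected = np.zeros(X.shape[1], dtype=bool)
        seen: set[frozenset] = set()
        for i in range(c1.shape[1]):
            surv = np.flatnonzero(c1[:, i] > 0)
            key = frozenset(surv.tolist())
            if not len(surv) or key in seen:
                continue
            seen.add(key)
            _, c2, _ = lasso_path(Xs[:, surv], ys, alphas=grid2 / 2.0)
            selected[surv] |= _admissible_any(np.abs(c2) > 0, q)
        return selected

    return sel


def _path_select_multi(X, y, a, grid, alpha, q):
    def sel(idx):
        Xs = _standardize(X[idx])
        Ys = _standardize(np.column_stack([y[idx], a[idx]]))
        active = np.zeros((X.shape[1], len(grid)), dtype=bool)
        B = None
        for i, lam in enumerate(grid):  # descending: warm starts along the path
            B, _ = _sgl_solve(Xs, Ys, alpha * lam, (1 - alpha) * lam, B0=B, tol=1e-6, max_iter=2000)
            active[:, i] = np.abs(B).sum(axis=1) > 0
        return _admissible_any(active, q)

    return sel


class StabilitySelection(BaseEstimator):
    """Stability-selection scoring of candidate enhancers for every gene.

    Parameters
    ----------
    variant : {"adaptive", "sequential", "multi_response"}
        Regression formulation refit on each subsample.
    coaccess : DataFrame or None
        Optional co-accessibility table (gene_id, peak_index, score) for the
        adaptive weights; otherwise the promoter-correlation fallback is used.
    n_subsamples, n_lambdas, lambda_min_ratio, sgl_alpha, weight_floor,
    random_state : see RegressionSpec.

    Attributes
    ----------
    pair_scores_ : DataFrame (gene_id, peak_index, score, method) where score
        is the enhancer's selection frequency in [0, 1]. Genes that a variant
        cannot handle (no promoter peak for sequential/multi_response) are
        skipped with a warning and absent from the table.
    """

    def __init__(
        self,
        variant="adaptive",
        coaccess=None,
        n_subsamples=100,
        n_lambdas=30,
        lambda_min_ratio=0.01,
        sgl_alpha=0.5,
        weight_floor=1e-3,
        max_active=None,
        random_state=0,
    ):
        self.variant = variant
        self.coaccess = coaccess
        self.n_subsamples = n_subsamples
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.sgl_alpha = sgl_alpha
        self.weight_floor = weight_floor
        self.max_active = max_active
        self.random_state = random_state

    def _spec(self) -> RegressionSpec:
        return RegressionSpec(
            variant=self.variant,
            n_subsamples=self.n_subsamples,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            sgl_alpha=self.sgl_alpha,
            weight_floor=self.weight_floor,
            max_active=self.max_active,
            seed=self.random_state,
        )

    def fit(self, data: MultiomeData, y=None):
        if self.variant not in {"adaptive", "sequential", "multi_response"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        expr, acc, pairs = data.expr, data.acc, data.pairs
        spec = self._spec()
        weights = None
        if self.variant == "adaptive":
            weights = compute_adaptive_weights(self.coaccess, acc, pairs, self.weight_floor)
        rows = []
        for gene in pairs.genes():
            X, yv, a, peaks = gene_design(expr, acc, pairs, gene)
            needs_promoter = self.variant in {"sequential", "multi_response"}
            if needs_promoter and a is None:
                warnings.warn(f"gene {gene}: no promoter peak; skipped by {self.variant}")
                continue
            Xs_full = _standardize(X)
            ys_full = _standardize(yv[:, None])[:, 0]
            q = spec.active_bound(len(peaks))
            if self.variant == "adaptive":
                phi = weights.loc[[(gene, int(p)) for p in peaks]].to_numpy(dtype=float)
                lam_max = lambda_max_lasso(Xs_full / phi[None, :], ys_full)
                sel_fn = _path_select_adaptive(X, yv, phi, _lambda_grid(lam_max, spec), q)
            elif self.variant == "sequential":
                as_full = _standardize(a[:, None])[:, 0]
                grid1 = _lambda_grid(lambda_max_lasso(Xs_full, as_full), spec)
                grid2 = _lambda_grid(lambda_max_lasso(Xs_full, ys_full), spec)
                sel_fn = _path_select_sequential(X, yv, a, grid1, grid2, q)
            else:
                as_full = _standardize(a[:, None])[:, 0]
                lam_max = sgl_lambda_max(Xs_full, np.column_stack([ys_full, as_full]), self.sgl_alpha)
                sel_fn = _path_select_multi(X, yv, a, _lambda_grid(lam_max, spec), self.sgl_alpha, q)
            freq = stability_select(sel_fn, expr.n_cells, len(peaks), spec)
            for p, f in zip(peaks, freq):
                rows.append((gene, int(p), float(f), self.variant))
        self.pair_scores_ = pd.DataFrame(rows, columns=["gene_id", "peak_index", "score", "method"])
        return self
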