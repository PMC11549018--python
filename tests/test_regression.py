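import numpy as np
import pandas as pd
import pytest

from geees.data_model import CandidatePairs, enumerate_candidates
from geees.regression import (
    RegressionSpec,
    StabilitySelection,
    _lasso,
    _sgl_solve,
    compute_adaptive_weights,
    fit_adaptive,
    fit_multi_response,
    fit_sequential,
    lambda_max_lasso,
    lasso_kkt_violation,
    stability_select,
)

from conftest import make_acc, make_expr


def cd_lasso_oracle(X, y, lam, weights=None, n_iter=5000):
    """Independent coordinate-descent solver for
    (1/C)||y - b0 - X b||^2 + lam * sum w_j |b_j| (public objective)."""
    C, E = X.shape
    w = np.ones(E) if weights is None else np.asarray(weights, float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b = np.zeros(E)
    col_sq = (Xc**2).sum(axis=0)
    for _ in range(n_iter):
        for j in range(E):
            if col_sq[j] == 0:
                continue
            r = yc - Xc @ b + Xc[:, j] * b[j]
            rho = Xc[:, j] @ r
            thr = lam * w[j] * C / 2.0
            b[j] = np.sign(rho) * max(abs(rho) - thr, 0) / col_sq[j]
    return b


def lasso_objective(X, y, b, lam, weights=None):
    C = len(y)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return ((yc - Xc @ b) ** 2).sum() / C + lam * (w * np.abs(b)).sum()


def _toy_design(seed=0, C=40, E=5, tss=1_000_000):
    """ExpressionMatrix/AccessibilityMatrix with one gene, E candidate peaks
    and a promoter peak, all accessibility drawn freely by the caller."""
    rng = np.random.default_rng(seed)
    X = (rng.random((E, C)) < 0.4).astype(float)
    prom = (rng.random(C) < 0.4).astype(float)
    y = rng.poisson(3.0, C).astype(float)
    return _build(y, X, prom, tss)


def _build(y, X, prom, tss=1_000_000):
    E, C = X.shape
    cells = [f"c{i}" for i in range(C)]
    tssdf = pd.DataFrame({"chrom": ["chr1"], "tss": [tss], "strand": ["+"]},
                         index=pd.Index(["g0"], name="gene_id"))
    expr = make_expr(np.asarray(y)[None, :], gene_ids=["g0"], cell_ids=cells, tss=tssdf)
    intervals = [("chr1", tss - 50, tss + 150)] + [
        ("chr1", tss + 10_000 * (i + 1), tss + 10_000 * (i + 1) + 500) for i in range(E)
    ]
    counts = np.vstack([prom[None, :], X])
    acc = make_acc(counts, intervals, cell_ids=cells)
    pairs = enumerate_candidates(expr, acc)
    assert pairs.promoter_peak["g0"] == 0 and len(pairs) == E
    return expr, acc, pairs


class TestAdaptiveWeights:
    def _pairs(self):
        table = pd.DataFrame({"gene_id": ["g0", "g0"], "peak_index": [1, 2],
                              "distance": [1000, 2000]})
        return CandidatePairs(table)

    def test_reciprocal_of_score(self):
        co = pd.DataFrame({"gene_id": ["g0"], "peak_index": [1], "score": [0.5]})
        w = compute_adaptive_weights(co, None, self._pairs())
        assert w.loc[("g0", 1)] == pytest.approx(2.0)

    def test_missing_score_gets_floor_weight(self):
        co = pd.DataFrame({"gene_id": ["g0"], "peak_index": [1], "score": [0.5]})
        w = compute_adaptive_weights(co, None, self._pairs())
        assert w.loc[("g0", 2)] == pytest.approx(1000.0)

    def test_fallback_identical_promoter_gives_unit_weight(self):
        prom = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0], dtype=float)
        X = np.vstack([prom, 1 - prom])
        expr, acc, pairs = _build(np.arange(10, dtype=float), X, prom)
        w = compute_adaptive_weights(None, acc, pairs)
        key = (("g0", int(pairs.table.peak_index.iloc[0])))
        assert w.loc[key] == pytest.approx(1.0)  # rho = 1 with itself
        # anti-correlated enhancer: non-positive score -> floor
        key2 = (("g0", int(pairs.table.peak_index.iloc[1])))
        assert w.loc[key2] == pytest.approx(1000.0)


class TestFitAdaptive:
    def test_unpenalized_single_predictor_recovers_slope(self):
        a = np.array([0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0], dtype=float)
        expr, acc, pairs = _build(2 * a, a[None, :], np.zeros(12))
        w = pd.Series([1.0], index=pd.MultiIndex.from_tuples(
            [("g0", int(pairs.table.peak_index.iloc[0]))]))
        beta = fit_adaptive("g0", expr, acc, pairs, w, lam=0.0)
        assert beta[0] == pytest.approx(2.0, abs=1e-10)

    def test_lambda_max_zeroes_everything(self):
        expr, acc, pairs = _toy_design(seed=1)
        peaks = pairs.table.peak_index
        w = pd.Series(np.ones(len(peaks)),
                      index=pd.MultiIndex.from_tuples([("g0", int(p)) for p in peaks]))
        from geees.regression import gene_design

        X, y, _, _ = gene_design(expr, acc, pairs, "g0")
        lam_max = lambda_max_lasso(X, y)
        beta = fit_adaptive("g0", expr, acc, pairs, w, lam=lam_max * 1.0001)
        assert np.all(beta == 0)

    def test_weighted_preference_between_identical_predictors(self):
        # two identical predictors, phi 1 vs 10: only the cheap one selected
        rng = np.random.default_rng(3)
        a = (rng.random(20) < 0.5).astype(float)
        X = np.vstack([a, a.copy()])
        X[1, 0] = 1 - X[1, 0]  # tiny perturbation to keep coordinates unique
        X[1] = a  # identical again; peaks differ by coordinates only
        y = 3 * a + rng.normal(0, 0.1, 20)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X, np.zeros(20))
        peaks = [int(p) for p in pairs.table.peak_index]
        w = pd.Series([1.0, 10.0], index=pd.MultiIndex.from_tuples(
            [("g0", p) for p in peaks]))
        from geees.regression import gene_design

        Xd, yd, _, _ = gene_design(expr, acc, pairs, "g0")
        lam = 0.25 * lambda_max_lasso(Xd, yd, weights=np.array([1.0, 10.0]))
        beta = fit_adaptive("g0", expr, acc, pairs, w, lam=lam)
        assert beta[0] != 0 and beta[1] == 0
        # cross-check against the coordinate-descent oracle's objective
        b_oracle = cd_lasso_oracle(Xd, yd, lam, weights=[1.0, 10.0])
        assert lasso_objective(Xd, yd, beta, lam, [1, 10]) <= (
            lasso_objective(Xd, yd, b_oracle, lam, [1, 10]) + 1e-6
        )

    def test_unit_weights_match_cd_oracle_objective(self):
        rng = np.random.default_rng(7)
        X = (rng.random((60, 6)) < 0.4).astype(float)
        y = X[:, 0] * 2 + X[:, 3] + rng.normal(0, 0.5, 60)
        lam = 0.3 * lambda_max_lasso(X, y)
        b = _lasso(X, y, lam)
        b_or = cd_lasso_oracle(X, y, lam)
        assert lasso_objective(X, y, b, lam) == pytest.approx(
            lasso_objective(X, y, b_or, lam), abs=1e-6
        )
        np.testing.assert_allclose(b, b_or, atol=1e-5)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(11)
        for seed in range(3):
            X = (rng.random((50, 8)) < 0.4).astype(float)
            y = X[:, 1] * 3 + rng.normal(0, 1, 50)
            for frac in (0.8, 0.3, 0.05):
                lam = frac * lambda_max_lasso(X, y)
                b = _lasso(X, y, lam)
                assert lasso_kkt_violation(X, y, b, lam) < 1e-6


class TestFitSequential:
    def test_unrelated_promoter_large_lambda_all_zero(self):
        expr, acc, pairs = _toy_design(seed=5)
        beta, surv = fit_sequential("g0", expr, acc, pairs, lambda1=1e6, lambda2=0.01)
        assert not surv.any() and np.all(beta == 0)

    def test_tracking_enhancer_survives_and_selected(self):
        rng = np.random.default_rng(6)
        a = (rng.random(60) < 0.5).astype(float)
        decoy = (rng.random(60) < 0.3).astype(float)
        X = np.vstack([a, decoy])
        y = 4 * a + rng.normal(0, 0.2, 60)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X, prom=a)
        beta, surv = fit_sequential("g0", expr, acc, pairs, lambda1=0.05, lambda2=0.05)
        assert surv[0] and beta[0] > 0

    def test_anticorrelated_promoter_coefficient_excluded(self):
        # enhancer anti-correlated with the promoter: stage-1 coefficient is
        # negative, so it is dropped even though it predicts expression
        rng = np.random.default_rng(9)
        a = (rng.random(80) < 0.5).astype(float)
        X = a[None, :]
        y = 5 * a + rng.normal(0, 0.2, 80)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X, prom=1 - a)
        beta, surv = fit_sequential("g0", expr, acc, pairs, lambda1=0.05, lambda2=0.01)
        assert not surv[0] and beta[0] == 0


class TestFitMultiResponse:
    def test_unpenalized_orthogonal_reduces_to_ols(self):
        # orthogonal binary predictors: the joint fit separates into two OLS
        X = np.zeros((40, 2))
        X[:20, 0] = 1
        X[np.arange(0, 40, 2), 1] = 1  # orthogonal to column 0 after centering
        rng = np.random.default_rng(2)
        y = 2 * X[:, 0] + rng.normal(0, 0.1, 40)
        a = np.maximum(3 * X[:, 1] + rng.normal(0, 0.1, 40), 0.0)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X.T, prom=a)
        beta, alpha = fit_multi_response("g0", expr, acc, pairs, 0.0, 0.0)
        Xc = X - X.mean(axis=0)
        yv = np.asarray(expr.counts.todense(), float).ravel()
        b_ols = np.linalg.lstsq(Xc, yv - yv.mean(), rcond=None)[0]
        a_ols = np.linalg.lstsq(Xc, a - a.mean(), rcond=None)[0]
        np.testing.assert_allclose(beta, b_ols, atol=1e-8)
        np.testing.assert_allclose(alpha, a_ols, atol=1e-8)

    def test_group_penalty_limit_zeroes_jointly(self):
        expr, acc, pairs = _toy_design(seed=4)
        beta, alpha = fit_multi_response("g0", expr, acc, pairs, 0.0, 1e6)
        assert np.all(beta == 0) and np.all(alpha == 0)

    def test_lambda2_zero_equals_two_independent_lassos(self):
        rng = np.random.default_rng(13)
        X = (rng.random((6, 50)) < 0.4).astype(float)
        prom = (rng.random(50) < 0.4).astype(float)
        y = 3 * X[0] + rng.normal(0, 0.3, 50)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X, prom)
        lam1 = 0.1
        beta, alpha = fit_multi_response("g0", expr, acc, pairs, lam1, 0.0)
        from geees.regression import gene_design

        Xd, yd, ad, _ = gene_design(expr, acc, pairs, "g0")
        # the joint loss is (1/(2C)) per response: equivalent single-response
        # lasso on the (1/C) scale uses lam = 2*lam1
        b_solo = _lasso(Xd, yd, 2 * lam1)
        a_solo = _lasso(Xd, ad, 2 * lam1)
        np.testing.assert_allclose(beta, b_solo, atol=1e-6)
        np.testing.assert_allclose(alpha, a_solo, atol=1e-6)

    def test_planted_group_beats_decoy_by_objective(self):
        # planted enhancer drives both responses; decoy drives neither.
        rng = np.random.default_rng(21)
        planted = (rng.random(30) < 0.5).astype(float)
        decoy = (rng.random(30) < 0.5).astype(float)
        X = np.vstack([planted, decoy])
        y = 4 * planted + rng.normal(0, 0.3, 30)
        prom = np.clip(planted + rng.normal(0, 0.2, 30), 0, None)
        expr, acc, pairs = _build(np.maximum(y, 0).round(), X, prom)
        beta, alpha = fit_multi_response("g0", expr, acc, pairs, 0.05, 0.05)
        assert abs(beta[0]) + abs(alpha[0]) > 0
        assert abs(beta[1]) + abs(alpha[1]) == 0
        # solution should not be improved by a projected-gradient oracle
        from geees.regression import gene_design

        Xd, yv, ad, _ = gene_design(expr, acc, pairs, "g0")
        Xc = Xd - Xd.mean(axis=0)
        Yc = np.column_stack([yv - yv.mean(), ad - ad.mean()])
        B_hat = np.column_stack([beta, alpha])

        def objective(B):
            C = Xc.shape[0]
            loss = ((Yc - Xc @ B) ** 2).sum() / (2 * C)
            return loss + 0.05 * np.abs(B).sum() + 0.05 * np.linalg.norm(B, axis=1).sum()

        rng2 = np.random.default_rng(0)
        best = objective(B_hat)
        for _ in range(300):  # random restarts + local proximal descent
            B = rng2.normal(0, 0.5, B_hat.shape)
            for _ in range(400):
                G = -Xc.T @ (Yc - Xc @ B) / Xc.shape[0]
                step = 0.5
                Z = B - step * G
                Z = np.sign(Z) * np.maximum(np.abs(Z) - step * 0.05, 0)
                nrm = np.linalg.norm(Z, axis=1, keepdims=True)
                scale = np.maximum(1 - step * 0.05 / np.maximum(nrm, 1e-12), 0)
                B = Z * scale
            best = min(best, objective(B))
        assert objective(B_hat) <= best + 1e-6


class TestStabilitySelect:
    def test_always_selected_gives_frequency_one(self):
        spec = RegressionSpec(n_subsamples=10, seed=0)
        freq = stability_select(lambda idx: np.array([True, False]), 20, 2, spec)
        np.testing.assert_allclose(freq, [1.0, 0.0])

    def test_failed_fits_excluded_from_denominator(self):
        spec = RegressionSpec(n_subsamples=10, seed=0)
        calls = []

        def fit(idx):
            calls.append(idx)
            return None if len(calls) % 2 else np.array([True])

        freq = stability_select(fit, 20, 1, spec)
        np.testing.assert_allclose(freq, [1.0])

    def test_subsamples_are_half_size_reproducible(self):
        spec = RegressionSpec(n_subsamples=5, seed=42)
        sizes = []
        stability_select(lambda idx: sizes.append(len(idx)) or np.array([False]), 21, 1, spec)
        assert sizes == [10] * 5

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            stability_select(lambda idx: np.array([True]), 3, 1, RegressionSpec())


class TestStabilitySelectionEstimator:
    @pytest.mark.parametrize("variant", ["adaptive", "sequential", "multi_response"])
    def test_planted_enhancer_outscores_decoys(self, data_small, truth_key, variant):
        est = StabilitySelection(variant, n_subsamples=25, random_state=0).fit(data_small)
        t = est.pair_scores_
        assert ((t["score"] >= 0) & (t["score"] <= 1)).all()
        planted_scores, decoy_scores = [], []
        for gene in {g for g, _ in truth_key}:
            sub = t[t.gene_id == gene]
            if sub.empty:
                continue
            is_planted = [(g, p) in truth_key for g, p in zip(sub.gene_id, sub.peak_index)]
            planted = sub[is_planted]
            decoys = sub[[not f for f in is_planted]]
            # at this sample size a lucky decoy can match the planted pair,
            # but the planted enhancer must clear the bulk of the decoys
            assert planted["score"].max() > decoys["score"].median()
            planted_scores.extend(planted["score"])
            decoy_scores.extend(decoys["score"])
        assert np.mean(planted_scores) > np.mean(decoy_scores) + 0.3

    def test_fixed_seed_reproducible(self, data_small):
        t1 = StabilitySelection("adaptive", n_subsamples=10, random_state=7).fit(data_small).pair_scores_
        t2 = StabilitySelection("adaptive", n_subsamples=10, random_state=7).fit(data_small).pair_scores_
        pd.testing.assert_frame_equal(t1, t2)

    def test_sgl_solver_converges_flag(self):
        rng = np.random.default_rng(1)
        Xc = rng.normal(size=(30, 4))
        Yc = rng.normal(size=(30, 2))
        B, conv = _sgl_solve(Xc - Xc.mean(0), Yc - Yc.mean(0), 0.05, 0.05)
        assert conv
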