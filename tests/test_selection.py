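"""Covariate-selection pipeline: correlation screen, GLM/BIC machinery, stepwise search."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from atlas import (backward_select, bic, fit_binomial_glm, flag_collinear_pairs,
                   pearson_matrix, resolve_collinear, vif_filter)
from atlas.selection import SelectionTrace, _with_intercept, select_covariates


def _simulate_glm_data(X, beta0, beta, m, rng):
    eta = beta0 + X @ np.asarray(beta)
    return rng.binomial(m, expit(eta))


class TestPearsonMatrix:
    def test_duplicated_column_gives_unit_correlation(self, rng):
        x = rng.normal(size=100)
        R = pearson_matrix(np.column_stack([x, x]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_orthogonalized_columns_near_zero(self, rng):
        A = rng.normal(size=(200, 3))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        R = pearson_matrix(Q)
        off = R[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 1e-12)

    def test_matches_brute_force_covariance_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        R = pearson_matrix(X)
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i], X[:, j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                assert R[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_constant_column_flagged(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            pearson_matrix(X)


class TestFlagCollinearPairs:
    def test_identity_matrix_empty(self):
        assert flag_collinear_pairs(np.eye(4)) == []

    def test_single_exceedance(self):
        R = np.eye(3)
        R[1, 2] = R[2, 1] = 0.85
        assert flag_collinear_pairs(R) == [(1, 2, 0.85)]

    def test_four_mutually_correlated_columns_give_six_pairs(self):
        R = np.full((4, 4), 0.9)
        np.fill_diagonal(R, 1.0)
        pairs = flag_collinear_pairs(R)
        assert len(pairs) == 6  # C(4,2)
        assert all(i < j for i, j, _ in pairs)

    def test_negative_correlation_flagged(self):
        R = np.eye(2)
        R[0, 1] = R[1, 0] = -0.95
        assert flag_collinear_pairs(R) == [(0, 1, -0.95)]


class TestBinomialGlm:
    def test_intercept_only_closed_form(self):
        y = np.full(40, 5.0)
        m = np.full(40, 20.0)
        fit = fit_binomial_glm(np.ones((40, 1)), y, m)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(logit(0.25), abs=1e-8)

    def test_binary_covariate_two_cell_closed_form(self):
        g = np.repeat([0.0, 1.0], 50)
        y = np.where(g == 0, 4.0, 12.0)  # prevalences 0.2 / 0.6 with m = 20
        m = np.full(100, 20.0)
        fit = fit_binomial_glm(np.column_stack([np.ones(100), g]), y, m)
        assert fit.coefficients[0] == pytest.approx(logit(0.2), abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(logit(0.6) - logit(0.2), abs=1e-8)

    def test_separation_flagged_not_silent(self):
        y = np.full(30, 10.0)
        m = np.full(30, 10.0)
        with pytest.warns(RuntimeWarning, match="converge"):
            fit = fit_binomial_glm(np.ones((30, 1)), y, m)
        assert not fit.converged

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial_glm(np.ones((3, 1)), np.array([5.0, 1, 1]), np.array([4.0, 4, 4]))


class TestBic:
    def test_direct_formula(self):
        from atlas.selection import GlmFit
        fit = GlmFit(np.zeros(3), log_likelihood=-100.0, n_obs=100, n_params=3,
                     converged=True)
        assert bic(fit) == pytest.approx(200 + 3 * np.log(100))
        assert bic(fit) == pytest.approx(213.81551, abs=1e-5)

    def test_penalty_monotone_in_params(self):
        from atlas.selection import GlmFit
        f2 = GlmFit(np.zeros(2), -50.0, 100, 2, True)
        f3 = GlmFit(np.zeros(3), -50.0, 100, 3, True)
        assert bic(f2) < bic(f3)

    def test_single_observation_no_penalty(self):
        from atlas.selection import GlmFit
        f = GlmFit(np.zeros(2), -7.0, 1, 2, True)
        assert bic(f) == pytest.approx(14.0)

    def test_unconverged_rejected(self):
        from atlas.selection import GlmFit
        f = GlmFit(np.zeros(1), -1.0, 10, 1, False)
        with pytest.raises(ValueError):
            bic(f)


class TestResolveCollinear:
    def test_no_flags_keeps_everything(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.binomial(10, 0.3, 50).astype(float)
        assert resolve_collinear(X, y, np.full(50, 10.0), []) == [0, 1, 2]

    def test_duplicated_pair_drops_exactly_one(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, x + rng.normal(0, 1e-8, 200), rng.normal(size=200)])
        y = rng.binomial(15, expit(x), 200).astype(float)
        pairs = flag_collinear_pairs(pearson_matrix(X))
        kept = resolve_collinear(X, y, np.full(200, 15.0), pairs)
        assert 2 in kept
        assert len([c for c in kept if c in (0, 1)]) == 1

    def test_true_predictor_usually_retained(self):
        # A drives the outcome, B = A + noise; A should win the pairwise BIC
        wins = 0
        n_rep = 200
        for s in range(n_rep):
            r = np.random.default_rng(10_000 + s)
            a = r.normal(size=150)
            b = a + r.normal(0, 0.35, 150)
            X = np.column_stack([a, b])
            y = r.binomial(22, expit(-0.5 + 1.0 * a), 150).astype(float)
            pairs = flag_collinear_pairs(pearson_matrix(X))
            assert pairs, "fixture must trigger the collinearity flag"
            kept = resolve_collinear(X, y, np.full(150, 22.0), pairs)
            wins += kept == [0]
        assert wins / n_rep >= 0.95

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 0.99 * x + rng.normal(0, 0.05, 100)])
        y = rng.binomial(10, expit(x), 100).astype(float)
        m = np.full(100, 10.0)
        pairs = flag_collinear_pairs(pearson_matrix(X))
        kept = resolve_collinear(X, y, m, pairs)
        Xk = X[:, kept]
        pairs2 = flag_collinear_pairs(pearson_matrix(Xk))
        assert resolve_collinear(Xk, y, m, pairs2) == list(range(len(kept)))


class TestVifFilter:
    def test_orthogonal_columns_untouched(self, rng):
        A = rng.normal(size=(100, 4))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        assert vif_filter(Q) == [0, 1, 2, 3]

    def test_exact_linear_combination_removed(self, rng):
        x1 = rng.normal(size=80)
        x2 = rng.normal(size=80)
        X = np.column_stack([x1, x2, x1 + x2])
        kept = vif_filter(X)
        assert len(kept) == 2

    def test_matches_ols_oracle(self, rng):
        from atlas.selection import _vifs
        X = rng.normal(size=(60, 3))
        X[:, 2] += 0.8 * X[:, 0]
        vifs = _vifs(X)
        for j in range(3):
            others = np.column_stack([np.ones(60), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            pred = others @ beta
            r2 = 1 - np.sum((X[:, j] - pred) ** 2) / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert vifs[j] == pytest.approx(1 / (1 - r2), rel=1e-10)

    def test_idempotent(self, rng):
        X = rng.normal(size=(100, 5))
        X[:, 4] = X[:, 0] + X[:, 1] + rng.normal(0, 0.1, 100)
        kept = vif_filter(X)
        assert vif_filter(X[:, kept]) == list(range(len(kept)))


class TestBackwardSelect:
    def test_single_useless_covariate_removed(self, rng):
        X = rng.normal(size=(300, 1))
        y = rng.binomial(20, 0.4, 300).astype(float)
        tr = backward_select(X, y, np.full(300, 20.0))
        assert tr.final_set == []
        assert len(tr.stepwise_path) == 1

    def test_null_covariates_mostly_dropped(self):
        empties = 0
        n_rep = 30
        for s in range(n_rep):
            r = np.random.default_rng(3000 + s)
            X = r.normal(size=(500, 4))
            y = r.binomial(22, 0.3, 500).astype(float)
            tr = backward_select(X, y, np.full(500, 22.0))
            for _, before, after in tr.stepwise_path:
                assert after < before
            empties += tr.final_set == []
        assert empties / n_rep >= 0.6

    def test_strong_covariate_retained(self):
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            r = np.random.default_rng(4000 + s)
            X = r.normal(size=(400, 6))
            y = r.binomial(22, expit(-0.5 + 1.0 * X[:, 0]), 400).astype(float)
            tr = backward_select(X, y, np.full(400, 22.0))
            hits += 0 in tr.final_set
        assert hits / n_rep >= 0.90

    def test_matches_exhaustive_minimum_bic_oracle(self):
        # small-p orthogonal design with well-separated effects
        r = np.random.default_rng(55)
        n, p = 600, 4
        A = r.normal(size=(n, p))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = Q * np.sqrt(n)
        y = r.binomial(22, expit(-0.8 + 1.2 * X[:, 0] - 0.9 * X[:, 1]), n).astype(float)
        m = np.full(n, 22.0)
        tr = backward_select(X, y, m)
        best_bic, best_set = np.inf, None
        for k in range(p + 1):
            for subset in itertools.combinations(range(p), k):
                b = bic(fit_binomial_glm(_with_intercept(X, list(subset)), y, m))
                if b < best_bic:
                    best_bic, best_set = b, sorted(subset)
        assert sorted(tr.final_set) == best_set
        # local optimality: no further single removal lowers BIC
        cur = bic(fit_binomial_glm(_with_intercept(X, tr.final_set), y, m))
        for drop in tr.final_set:
            rest = [c for c in tr.final_set if c != drop]
            assert bic(fit_binomial_glm(_with_intercept(X, rest), y, m)) >= cur

    def test_empty_design_returns_intercept_only_trace(self):
        y = np.array([3.0, 4.0, 5.0])
        tr = backward_select(np.empty((3, 0)), y, np.full(3, 10.0))
        assert tr.final_set == []
        assert tr.stepwise_path == []


class TestFullPipeline:
    def test_trace_consistency_and_determinism(self, rng):
        x1 = rng.normal(size=300)
        x2 = x1 + rng.normal(0, 0.2, 300)          # collinear with x1
        x3 = rng.normal(size=300)
        x4 = x1 + x3 + rng.normal(0, 0.05, 300)    # high VIF
        X = np.column_stack([x1, x2, x3, x4])
        y = rng.binomial(22, expit(-1 + x1), 300).astype(float)
        m = np.full(300, 22.0)
        tr1 = select_covariates(X, y, m)
        tr2 = select_covariates(X, y, m)
        assert tr1.final_set == tr2.final_set  # no RNG anywhere
        tr1.validate()
        dropped = set(tr1.dropped_by_bic) | {i for i, _ in tr1.dropped_by_vif}
        assert not set(tr1.final_set) & dropped

    def test_trace_invariant_rejects_overlap(self):
        tr = SelectionTrace(final_set=[1], dropped_by_bic=[1])
        with pytest.raises(ValueError):
            tr.validate()
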