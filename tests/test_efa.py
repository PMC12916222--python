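import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dysmap import efa, synthetic
from dysmap.efa import (benjamini_hochberg, correlation_matrix, factor_scores,
                        fit_efa, group_compare_factors, mann_whitney_u,
                        minres_factor, promax_rotate, rank_biserial,
                        select_n_factors)


def build_corr(loadings, phi=None):
    """Population correlation matrix from a factor model (unit diagonal)."""
    if phi is None:
        phi = np.eye(loadings.shape[1])
    R = loadings @ phi @ loadings.T
    np.fill_diagonal(R, 1.0)
    return R


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=(20, 1))
        X = np.hstack([x, x, np.random.default_rng(1).normal(size=(20, 1))])
        R = correlation_matrix(X)
        assert R[0, 1] == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5],
                      [3.0, 5.0, 2.0], [4.0, 3.0, 0.0]])
        R = correlation_matrix(X)
        for i, j in itertools.combinations(range(3), 2):
            xi, xj = X[:, i], X[:, j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean()) ** 2)
                          * np.sum((xj - xj.mean()) ** 2))
            assert R[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_pairwise_complete_with_missing_cell(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        X[0, 1] = np.nan
        R = correlation_matrix(X)
        mask = ~np.isnan(X[:, 1])
        expected = np.corrcoef(X[mask, 0], X[mask, 1])[0, 1]
        assert R[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_named_in_error(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match="2"):
            correlation_matrix(X)


class TestSelectNFactors:
    def test_identity_spectrum(self):
        k, eigvals = select_n_factors(np.eye(31))
        assert k == 0
        assert np.allclose(eigvals, 1.0)

    def test_block_diagonal_closed_form(self):
        """4 blocks with within-block r=0.6: top eigenvalues 1+(m-1)*0.6."""
        sizes = [8, 8, 8, 7]
        blocks = []
        for m in sizes:
            B = np.full((m, m), 0.6)
            np.fill_diagonal(B, 1.0)
            blocks.append(B)
        R = scipy.linalg.block_diag(*blocks)
        k, eigvals = select_n_factors(R)
        assert k == 4
        expected_top = sorted([1 + (m - 1) * 0.6 for m in sizes], reverse=True)
        assert np.allclose(eigvals[:4], expected_top, atol=1e-10)

    def test_recommends_planted_four_on_synthetic_battery(self):
        cohort = synthetic.simulate_cohort(seed=3, include_timeseries=False)
        R = correlation_matrix(cohort.behavior.to_numpy())
        k, _ = select_n_factors(R)
        assert k == 4


class TestMinres:
    def test_exact_one_factor_recovery(self):
        lam = np.full((10, 1), 0.8)
        R = build_corr(lam)
        L, uniq = minres_factor(R, 1)
        assert np.allclose(np.abs(L[:, 0]), 0.8, atol=1e-4)
        assert np.allclose(uniq + np.sum(L ** 2, axis=1), 1.0, atol=1e-6)

    def test_noiseless_planted_four_factor_fit_is_exact(self):
        truth = synthetic.default_behavior_truth(seed=1)
        R = build_corr(truth.loadings, truth.phi)
        L, _ = minres_factor(R, 4)
        resid = R - L @ L.T
        np.fill_diagonal(resid, 0.0)
        assert np.sum(resid ** 2) < 1e-6

    def test_objective_dominates_principal_axis_start(self):
        """The minres optimum beats a one-shot principal-axis solution."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        R = np.corrcoef(A @ A.T + 3 * np.eye(6))
        # principal-axis: SMC communalities, single eigendecomposition
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        Rh = R - np.diag(1.0 - smc)
        w, Q = np.linalg.eigh(Rh)
        idx = np.argsort(w)[::-1][:2]
        L_pa = Q[:, idx] * np.sqrt(np.maximum(w[idx], 0))

        def offdiag_ss(L):
            E = R - L @ L.T
            np.fill_diagonal(E, 0.0)
            return np.sum(E ** 2)

        L_mr, _ = minres_factor(R, 2)
        assert offdiag_ss(L_mr) <= offdiag_ss(L_pa) + 1e-12

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            minres_factor(np.eye(5), 5)


class TestPromax:
    def test_perfect_simple_structure_is_a_fixed_point(self):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.8
        L[4:, 1] = 0.7
        B, phi = promax_rotate(L, 4)
        # invariant up to column permutation/sign
        best = 0.0
        for perm in itertools.permutations(range(2)):
            for signs in itertools.product([1, -1], repeat=2):
                cand = B[:, perm] * signs
                best = max(best, -np.max(np.abs(cand - L)))
        assert best > -1e-6

    def test_orthogonal_structure_keeps_phi_near_identity(self):
        rng = np.random.default_rng(3)
        L = np.zeros((12, 2))
        L[:6, 0] = rng.uniform(0.6, 0.9, 6)
        L[6:, 1] = rng.uniform(0.6, 0.9, 6)
        R = build_corr(L)
        L0, _ = minres_factor(R, 2)
        _, phi = promax_rotate(L0, 4)
        assert abs(phi[0, 1]) < 0.05

    def test_oblique_recovery_of_planted_phi(self):
        """Planted factor correlation 0.5 recovered within 0.1 (noiseless)."""
        L = np.zeros((8, 2))
        L[:4, 0] = [0.8, 0.75, 0.7, 0.65]
        L[4:, 1] = [0.78, 0.72, 0.68, 0.6]
        phi_true = np.array([[1.0, 0.5], [0.5, 1.0]])
        R = build_corr(L, phi_true)
        L0, _ = minres_factor(R, 2)
        B, phi = promax_rotate(L0, 4)
        assert phi[0, 1] == pytest.approx(0.5, abs=0.1)
        # pattern recovered up to permutation
        err = min(np.max(np.abs(B[:, list(p)] - L))
                  for p in itertools.permutations(range(2)))
        assert err < 0.05

    def test_sign_convention(self):
        L = np.zeros((6, 2))
        L[:3, 0] = -0.8
        L[3:, 1] = 0.7
        B, _ = promax_rotate(L, 4)
        for j in range(2):
            assert B[np.argmax(np.abs(B[:, j])), j] > 0

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            promax_rotate(np.ones((4, 2)), 0.5)


class TestFactorScores:
    def test_noiseless_recovery_of_true_factors(self):
        participants = synthetic.simulate_participants((50, 50, 50), seed=2)
        truth = synthetic.default_behavior_truth(seed=2)
        X, F = synthetic.simulate_behavior(participants, truth, seed=3,
                                           noise_scale=0.0, return_factors=True)
        sol = fit_efa(X.to_numpy(), 4)
        C = np.abs(np.corrcoef(sol.scores.T, F.to_numpy().T)[:4, 4:])
        best = max(sum(C[i, p[i]] for i in range(4))
                   for p in itertools.permutations(range(4)))
        assert best / 4 >= 0.99

    def test_row_at_column_means_scores_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        X[0] = X[1:].mean(axis=0)  # fixed point: row 0 equals the column means
        assert np.allclose(X[0], X.mean(axis=0))
        R = correlation_matrix(X)
        L, _ = minres_factor(R, 2)
        B, phi = promax_rotate(L, 4)
        s = factor_scores(X, B, phi, R=R)
        assert np.allclose(s[0], 0.0, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        R = correlation_matrix(X)
        L, _ = minres_factor(R, 2)
        B, phi = promax_rotate(L, 4)
        s = factor_scores(X, B, phi, R=R)
        perm = rng.permutation(30)
        s_perm = factor_scores(X[perm], B, phi, R=R)
        assert np.allclose(s_perm, s[perm], atol=1e-10)

    def test_singular_correlation_suggests_smoothing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 10))  # fewer rows than columns -> singular R
        R = correlation_matrix(X)
        L = np.zeros((10, 2))
        L[:5, 0] = L[5:, 1] = 0.7
        with pytest.raises(RuntimeError, match="smooth"):
            factor_scores(X, L, np.eye(2), R=R)
        s = factor_scores(X, L, np.eye(2), R=efa.smooth_correlation(R, 1e-4))
        assert np.all(np.isfinite(s))

    def test_incomplete_rows_flagged_nan(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        X[3, 2] = np.nan
        R = correlation_matrix(X)
        L, _ = minres_factor(R, 2)
        B, phi = promax_rotate(L, 4)
        s = factor_scores(X, B, phi, R=R)
        assert np.all(np.isnan(s[3]))
        assert not np.any(np.isnan(np.delete(s, 3, axis=0)))


def enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_textbook_example(self):
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_zero_rbc(self):
        U, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert rank_biserial(U, 3, 3) == pytest.approx(0.0)

    def test_exact_p_equals_full_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=8)
        y = rng.normal(size=9) + 0.5
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(9)
        x = np.round(rng.normal(size=30), 1)  # forces ties
        y = np.round(rng.normal(size=30), 1)
        U, p = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRankBiserial:
    @pytest.mark.parametrize("U,n1,n2,expected", [
        (6.0, 3, 4, 0.0),       # U = n1 n2 / 2
        (0.0, 5, 5, 1.0),
        (25.0, 5, 5, -1.0),
        (29.0, 47, 37, 1 - 58 / 1739),   # ~0.9667
    ])
    def test_formula(self, U, n1, n2, expected):
        assert rank_biserial(U, n1, n2) == pytest.approx(expected)

    def test_invalid_u_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial(26.0, 5, 5)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        adj, rej = benjamini_hochberg([0.01, 0.02, 0.03], 0.05)
        assert np.allclose(adj, [0.03, 0.03, 0.03])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, _ = benjamini_hochberg([0.2], 0.05)
        assert adj[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_manual_step_up(self, pvals):
        adj, rej = benjamini_hochberg(pvals, 0.05)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            manual[i] = running
        assert np.allclose(adj, manual, atol=1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2], 0.05)


class TestGroupCompare:
    def test_table_shape_and_invariants(self):
        participants = synthetic.simulate_participants((8, 8, 8), seed=1)
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(24, 4))
        table = group_compare_factors(scores, participants, q=0.05)
        assert len(table) == 3 * 4
        assert (table["p_fdr"] >= table["p"] - 1e-12).all()
        assert table["rbc"].abs().le(1).all()
        assert table["U"].between(0, 8 * 8).all()

    def test_planted_shift_detected_with_high_power(self):
        detected = others_flagged = 0
        n_sims = 20
        for sim in range(n_sims):
            participants = synthetic.simulate_participants((40, 40, 40),
                                                           seed=3000 + sim)
            rng = np.random.default_rng(4000 + sim)
            scores = rng.normal(size=(120, 4))
            ieo = (participants["group"] == "ADHD_IEO").to_numpy()
            scores[ieo, 0] += 1.0
            table = group_compare_factors(scores, participants, q=0.05)
            hit = table[(table["factor"] == 1) & (table["group2"] == "ADHD_IEO")
                        & (table["group1"] == "ADHD")]["significant"].item()
            detected += hit
            others_flagged += table[(table["factor"] != 1)]["significant"].sum()
        assert detected >= 0.9 * n_sims
        assert others_flagged <= 0.15 * n_sims * 9  # 9 null rows per sim

    def test_too_small_group_rejected(self):
        participants = synthetic.simulate_participants((2, 2, 2), seed=0)
        participants = participants.iloc[1:]  # NT has 1 member
        with pytest.raises(ValueError):
            group_compare_factors(np.zeros((5, 2)), participants)
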