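"""Rank-2 machinery: decompositions, A-matrices, and every bound."""

import math

import numpy as np
import pytest

from phenoswitch import (
    EnvironmentParams,
    MuParameters,
    build_a_map,
    decompose,
    hl_lower_bound,
    improved_upper_bound,
    lower_bound_markov,
    lower_bound_trace,
    lyapunov_rank1,
    lyapunov_stochastic_rank1,
    make_general,
    make_stochastic,
    mc_lyapunov,
    norm_bounds,
    optimize_lower_bound_markov,
    upper_bound_spectral,
)
from phenoswitch.environment import simulate_path
from phenoswitch.lyapunov_bounds import (
    _theta_mu,
    a_product_log_norm,
    type_path_scores,
    variational_objective,
)

from conftest import delta_pair, nabla_pair


class TestDecompose:
    @pytest.mark.parametrize("flavor", ["rows", "columns", "posdet", "negdet"])
    def test_reconstruction(self, flavor):
        rng = np.random.default_rng(3)
        for _ in range(50):
            M = rng.uniform(0.1, 3, (2, 2))
            det = np.linalg.det(M)
            if flavor == "posdet" and det < 0:
                M = M.T if np.linalg.det(M.T) >= 0 else M[[1, 0]]
            if flavor == "negdet" and np.linalg.det(M) > 0:
                M = M[[1, 0]]
            fac = decompose(M, flavor)
            np.testing.assert_allclose(fac.reconstruct(), M, atol=1e-12)
            for v in (fac.l1, fac.r1, fac.l2, fac.r2):
                assert np.all(v >= 0)

    def test_rows_flavor_structure(self):
        fac = decompose(np.array([[1.0, 2.0], [3.0, 4.0]]), "rows")
        np.testing.assert_allclose(fac.l1, [1, 0])
        np.testing.assert_allclose(fac.r1, [1, 2])

    def test_posdet_on_delta_matrix(self):
        # e = 1 matrix: a = 13/4, det = 1, second right vector (0, det/a)
        M = delta_pair(0.05).M1
        fac = decompose(M, "posdet")
        np.testing.assert_allclose(fac.r2, [0, 4 / 13], atol=1e-12)

    def test_flavor_determinant_mismatch(self):
        neg = nabla_pair(0.05).M1  # det = -1
        with pytest.raises(ValueError):
            decompose(neg, "posdet")
        pos = delta_pair(0.05).M1  # det = +1
        with pytest.raises(ValueError):
            decompose(pos, "negdet")


class TestAMatrixMap:
    def test_rows_flavor_gives_first_matrix(self, delta_005):
        amap = build_a_map(delta_005, "rows")
        for i in (1, 2):
            for j in (1, 2):
                np.testing.assert_allclose(
                    amap[(i, j)], delta_005.matrix(i), atol=1e-12
                )

    def test_columns_flavor_gives_second_matrix(self, delta_005):
        amap = build_a_map(delta_005, "columns")
        for i in (1, 2):
            for j in (1, 2):
                np.testing.assert_allclose(
                    amap[(i, j)], delta_005.matrix(j), atol=1e-12
                )

    def test_negdet_flavor_closed_form(self, nabla_005):
        # A(i,j) = [[tr M(j), 1], [-det M(j), 0]]
        amap = build_a_map(nabla_005, "negdet")
        for i in (1, 2):
            for j in (1, 2):
                Mj = nabla_005.matrix(j)
                expected = np.array(
                    [[np.trace(Mj), 1.0], [-np.linalg.det(Mj), 0.0]]
                )
                np.testing.assert_allclose(amap[(i, j)], expected, atol=1e-12)

    @pytest.mark.parametrize(
        "flavors", [("rows", None), ("columns", None), ("auto", None)]
    )
    def test_a_product_exponent_matches_m_product(self, env_iid, flavors):
        # the A-reduction preserves the exponent for every flavor
        for pair in (delta_pair(0.05), nabla_pair(0.05)):
            amap = build_a_map(pair, flavors[0], flavors[1])
            path = simulate_path(env_iid, 10_001, seed=23)
            a_est = a_product_log_norm(amap, path) / (len(path) - 1)
            m_est = mc_lyapunov(pair, env_iid, n_steps=10_000, n_reps=8, seed=24)
            assert abs(a_est - m_est.value) < 4 * max(m_est.stderr, 1e-3)


class TestSpectralUpper:
    def test_dominates_exact_on_rank1_pairs(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 100:
            s1, s2 = rng.uniform(0.05, 0.99, 2)
            env = EnvironmentParams(s1, s2)
            m_a, m_d, w = rng.uniform(0.3, 3, 3)
            stay = w * m_d / m_a
            if w + stay > 1:
                continue
            pair = make_stochastic(m_a, m_d, 0.1, w, w, 1 - w - stay, 1 - w - stay)
            exact = lyapunov_rank1(pair, env).value
            bound = upper_bound_spectral(build_a_map(pair), env, "one").value
            assert bound >= exact - 1e-10
            checked += 1

    def test_constant_pair_recovers_log_perron(self):
        M = np.array([[1.2, 0.3], [0.4, 0.7]])
        pair = make_general(M, M, "constant")
        env = EnvironmentParams(0.4, 0.3)
        bound = upper_bound_spectral(build_a_map(pair), env, "one").value
        rho = float(np.max(np.abs(np.linalg.eigvals(M))))
        assert bound == pytest.approx(math.log(rho), abs=1e-10)

    def test_perron_scaling_bounds_mc(self, env_iid, delta_005):
        bound = upper_bound_spectral(build_a_map(delta_005), env_iid, "perron").value
        est = mc_lyapunov(delta_005, env_iid, n_steps=20_000, n_reps=8, seed=31)
        assert bound >= est.value - 3 * est.stderr

    def test_invalid_lambda(self, env_iid, delta_005):
        amap = build_a_map(delta_005)
        with pytest.raises(ValueError):
            upper_bound_spectral(amap, env_iid, {(1, 1): 0.0, (1, 2): 1, (2, 1): 1, (2, 2): 1})


class TestTraceLower:
    def test_closed_form_value_on_delta(self, env_iid, delta_005):
        # tr M(1) = 3.65, tr M(2) = 0.5625, det M(1)/m_a = 4/13
        got = lower_bound_trace(delta_005, env_iid).value
        expected = 0.5 * math.log(3.65 - 4 / 13) + 0.5 * math.log(0.5625 - 4 / 13)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_reduces_to_exact_at_zero_determinant(self, env_rare, stochastic_pair):
        bound = lower_bound_trace(stochastic_pair, env_rare).value
        exact = lyapunov_stochastic_rank1(2, 2, 1 / 20, 0.4, 0.4, env_rare).value
        assert bound == pytest.approx(exact, abs=1e-12)

    def test_below_mc_on_alpha_grid(self, env_iid):
        for alpha in (0.02, 0.1, 0.2):
            for mk in (delta_pair, nabla_pair):
                pair = mk(alpha)
                bound = lower_bound_trace(pair, env_iid).value
                est = mc_lyapunov(pair, env_iid, n_steps=10_000, n_reps=8, seed=41)
                assert bound <= est.value + 3 * est.stderr

    def test_requires_shared_dormant_row(self, env_iid):
        pair = make_stochastic(2, 2, 0.1, 0.4, 0.3, 0.2, 0.3)
        with pytest.raises(ValueError):
            lower_bound_trace(pair, env_iid)


class TestMarkovLower:
    def test_theta_choice_reproduces_retrospective_bound(self, env_iid, delta_005, nabla_005):
        for pair in (delta_005, nabla_005):
            amap = build_a_map(pair, "rows")
            mu, _, _ = _theta_mu(pair)
            direct = lower_bound_markov(amap, env_iid, mu).value
            hl = hl_lower_bound(pair, env_iid).value
            assert direct == pytest.approx(hl, abs=1e-9)

    def test_any_mu_stays_below_mc(self, env_iid, nabla_005):
        amap = build_a_map(nabla_005, "rows")
        est = mc_lyapunov(nabla_005, env_iid, n_steps=20_000, n_reps=8, seed=51)
        rng = np.random.default_rng(52)
        for _ in range(20):
            mu = MuParameters(rng.random((2, 2, 2)))
            bound = lower_bound_markov(amap, env_iid, mu).value
            assert bound <= est.value + 3 * est.stderr

    def test_degenerate_mu_gives_stationary_log_diagonal(self, env_rare, stochastic_pair):
        # mu == 1 keeps the chain in type 1: pi-weighted log of the (1,1)
        # entries of A, below the exact value
        amap = build_a_map(stochastic_pair, "rows")
        mu = MuParameters(np.ones((2, 2, 2)))
        got = lower_bound_markov(amap, env_rare, mu).value
        pi1 = env_rare.s2 / (env_rare.s1 + env_rare.s2)
        expected = pi1 * math.log(amap[(1, 1)][0, 0]) + (1 - pi1) * math.log(
            amap[(2, 2)][0, 0]
        )
        assert got == pytest.approx(expected, abs=1e-12)
        exact = lyapunov_stochastic_rank1(2, 2, 1 / 20, 0.4, 0.4, env_rare).value
        assert got <= exact + 1e-12


class TestOptimizer:
    def test_includes_theta_candidate(self, env_iid, nabla_005):
        amap = build_a_map(nabla_005, "rows")
        hl = hl_lower_bound(nabla_005, env_iid).value
        best, _ = optimize_lower_bound_markov(amap, env_iid, n_draws=50, seed=6)
        assert best.value >= hl - 1e-12

    def test_monotone_in_draws_under_nested_seed(self, env_iid, delta_005):
        amap = build_a_map(delta_005, "rows")
        vals = [
            optimize_lower_bound_markov(amap, env_iid, n_draws=n, seed=7)[0].value
            for n in (10, 50, 200)
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_below_mc(self, env_iid, delta_005):
        amap = build_a_map(delta_005, "rows")
        best, _ = optimize_lower_bound_markov(amap, env_iid, n_draws=200, seed=8)
        est = mc_lyapunov(delta_005, env_iid, n_steps=20_000, n_reps=8, seed=9)
        assert best.value <= est.value + 3 * est.stderr


class TestRetrospectiveBound:
    def test_slow_environment_limit(self, delta_005):
        # s -> 0 at fixed ratio: bound -> pi-weighted E[log perron]
        from phenoswitch import perron_root

        rho1 = perron_root(delta_005.M1)
        rho2 = perron_root(delta_005.M2)
        ratio = 2.0
        target = (math.log(rho1) + ratio * math.log(rho2)) / (1 + ratio)
        got = hl_lower_bound(delta_005, EnvironmentParams(2e-6, 1e-6)).value
        assert got == pytest.approx(target, abs=1e-4)

    def test_constant_pair_gives_log_perron(self):
        M = np.array([[1.2, 0.3], [0.4, 0.7]])
        pair = make_general(M, M, "constant")
        from phenoswitch import perron_root

        got = hl_lower_bound(pair, EnvironmentParams(0.4, 0.3)).value
        assert got == pytest.approx(math.log(perron_root(M)), abs=1e-10)

    def test_reducible_matrix_rejected(self, responsive_pair, env_iid):
        with pytest.raises(ValueError):
            hl_lower_bound(responsive_pair, env_iid)


class TestNormBounds:
    def test_permanent_oracle(self):
        M = np.array([[2.0, 2.0], [0.4, 0.4]])
        from phenoswitch.lyapunov_mc import SUPER_MULTIPLICATIVE

        assert SUPER_MULTIPLICATIVE["permanent"](M) == pytest.approx(1.6)

    def test_diagonal_lower_below_exact(self, env_rare, stochastic_pair):
        lo, _ = norm_bounds(stochastic_pair, env_rare, which="diagonal")
        exact = lyapunov_stochastic_rank1(2, 2, 1 / 20, 0.4, 0.4, env_rare).value
        assert lo.value <= exact + 1e-12

    def test_upper_above_mc_on_delta(self, env_iid, delta_005):
        _, up = norm_bounds(delta_005, env_iid, norm="l1")
        est = mc_lyapunov(delta_005, env_iid, n_steps=10_000, n_reps=8, seed=61)
        assert up.value >= est.value - 3 * est.stderr


class TestImprovedUpper:
    def test_psi_nonpositive_random_pairs(self):
        rng = np.random.default_rng(71)
        env = EnvironmentParams(0.4, 0.3)
        for _ in range(50):
            pair = make_general(rng.uniform(0.05, 3, (2, 2)), rng.uniform(0.05, 3, (2, 2)))
            plain = norm_bounds(pair, env)[1].value
            improved = improved_upper_bound(pair, env).value
            assert improved <= plain + 1e-12

    def test_beats_spectral_bound_somewhere_on_alpha_grid(self, env_fast):
        # active-leaning pair in the fast regime: for sufficiently small
        # alpha the corrected l1-norm bound undercuts the perron-scaled
        # spectral bound
        wins = []
        for alpha in (0.001, 0.002, 0.005, 0.01, 0.05):
            pair = delta_pair(alpha)
            imp = improved_upper_bound(pair, env_fast, norm="l1").value
            spec = upper_bound_spectral(build_a_map(pair, "rows"), env_fast, "perron").value
            wins.append(imp < spec)
        assert any(wins)


class TestBracketing:
    def test_all_bounds_bracket_mc(self, env_iid, env_rare, env_fast):
        # max(lower bounds) <= MC +- 3 s.e. <= min(upper bounds)
        for env in (env_iid, env_rare, env_fast):
            for mk in (delta_pair, nabla_pair):
                pair = mk(0.05)
                amap = build_a_map(pair, "rows")
                lowers = [
                    lower_bound_trace(pair, env).value,
                    hl_lower_bound(pair, env).value,
                    norm_bounds(pair, env)[0].value,
                ]
                uppers = [
                    upper_bound_spectral(amap, env, "perron").value,
                    upper_bound_spectral(amap, env, "one").value,
                    improved_upper_bound(pair, env).value,
                    norm_bounds(pair, env)[1].value,
                ]
                est = mc_lyapunov(pair, env, n_steps=20_000, n_reps=8, seed=81)
                assert max(lowers) <= est.value + 3 * est.stderr
                assert min(uppers) >= est.value - 3 * est.stderr

    def test_rank1_pair_bracketed_by_all_bounds(self, env_iid, stochastic_pair):
        exact = lyapunov_rank1(stochastic_pair, env_iid).value
        amap = build_a_map(stochastic_pair, "rows")
        assert lower_bound_trace(stochastic_pair, env_iid).value <= exact + 1e-10
        assert norm_bounds(stochastic_pair, env_iid)[0].value <= exact + 1e-10
        assert hl_lower_bound(stochastic_pair, env_iid).value <= exact + 1e-10
        assert upper_bound_spectral(amap, env_iid, "one").value >= exact - 1e-10
        assert improved_upper_bound(stochastic_pair, env_iid).value >= exact - 1e-10


class TestGibbsDuality:
    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_variational_supremum_equals_log_norm(self, env_iid, nabla_005, n):
        # brute force over all 2^n type paths: the Gibbs measure attains
        # sup_nu (E_nu[score] + H(nu)) = log ||A-product||_sum, and no
        # other density exceeds it
        amap = build_a_map(nabla_005, "rows")
        path = simulate_path(env_iid, n, seed=n)
        scores = type_path_scores(amap, path)
        target = a_product_log_norm(amap, path)
        # log-sum-exp of the scores equals the log norm of the product
        m = scores.max()
        lse = m + math.log(np.exp(scores - m).sum())
        assert lse == pytest.approx(target, abs=1e-10)
        gibbs = np.exp(scores - lse)
        attained = variational_objective(scores, gibbs)
        assert attained == pytest.approx(target, abs=1e-10)
        rng = np.random.default_rng(n)
        for _ in range(50):
            nu = rng.dirichlet(np.ones(len(scores)))
            assert variational_objective(scores, nu) <= target + 1e-9
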