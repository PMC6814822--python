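"""OU/BM likelihoods, weight matrices, AICc machinery, bootstrap, ancestral states."""

import math

import numpy as np
import pytest
from scipy import stats

from ssdevol import (
    read_tree,
    simulate_tree,
    OUModel,
    ou_weight_matrix,
    ou_vcv,
    aicc,
    aicc_weights,
    half_life,
    compare_models,
    parametric_bootstrap,
    bm_ancestral_states,
)
from ssdevol.tree import SimmapTree
from ssdevol.markov import build_q
from ssdevol.simulate import simulate_regimes, simulate_trait


def two_regime_map(tree, branch, pos_frac=0.5, states=("bg", "shift")):
    """Paint a two-regime history: `states[1]` from a point on `branch` tipward."""
    insub = [False] * tree.n_nodes
    insub[branch] = True
    for v in tree.preorder:
        if v != tree.root and insub[tree.parent[v]]:
            insub[v] = True
    segs = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        L = float(tree.lengths[v])
        if v == tree.root:
            segs[v] = [(states[0], 0.0)]
        elif v == branch:
            segs[v] = [(states[0], L * pos_frac), (states[1], L * (1 - pos_frac))]
        elif insub[v]:
            segs[v] = [(states[1], L)]
        else:
            segs[v] = [(states[0], L)]
    return SimmapTree(tree, segs, alphabet=states)


@pytest.fixture
def mapped_tree():
    tree = simulate_tree(30, 12.0, seed=50)
    sm = simulate_regimes(tree, build_q("ER", [0.08], 3), ("a", "b", "c"), "a", seed=51)
    return sm


class TestWeightMatrix:
    def test_single_regime_all_weight(self):
        tree = simulate_tree(10, 8.0, seed=52)
        sm = simulate_regimes(tree, np.zeros((1, 1)), ("only",), "only", seed=1)
        W, regimes = ou_weight_matrix(sm, alpha=0.7)
        np.testing.assert_allclose(W[:, regimes.index("only")], 1.0, atol=1e-12)

    def test_large_alpha_terminal_regime(self, mapped_tree):
        alpha = 1e3 / mapped_tree.tree.depth
        W, regimes = ou_weight_matrix(mapped_tree, alpha)
        tips = mapped_tree.tip_states()
        for i, lab in enumerate(mapped_tree.tree.tip_labels):
            assert W[i, regimes.index(tips[lab])] >= 0.999

    @pytest.mark.parametrize("alpha", [0.0, 0.03, 0.4, 2.0])
    def test_rows_sum_to_one_exactly(self, mapped_tree, alpha):
        W, _ = ou_weight_matrix(mapped_tree, alpha)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_three_segment_history_vs_quadrature(self):
        """Segment weights match fine Riemann integration of alpha e^(-alpha(T-s))."""
        tree = read_tree("(A:10,B:10);")
        a, b = tree.tip_index("A"), tree.tip_index("B")
        segs = [None] * tree.n_nodes
        segs[tree.root] = [("r1", 0.0)]
        segs[a] = [("r1", 3.0), ("r2", 4.5), ("r1", 2.5)]
        segs[b] = [("r1", 10.0)]
        sm = SimmapTree(tree, segs, alphabet=("r1", "r2"))
        alpha, T = 0.37, 10.0
        W, regimes = ou_weight_matrix(sm, alpha)
        n_steps = 100_000
        s = (np.arange(n_steps) + 0.5) * (T / n_steps)
        dens = alpha * np.exp(-alpha * (T - s)) * (T / n_steps)
        in_r2 = (s >= 3.0) & (s < 7.5)
        w2 = dens[in_r2].sum()
        w1 = dens[~in_r2].sum() + math.exp(-alpha * T)
        assert W[a, regimes.index("r2")] == pytest.approx(w2, abs=1e-7)
        assert W[a, regimes.index("r1")] == pytest.approx(w1, abs=1e-7)


class TestOUCovariance:
    def test_bm_limit(self, yule20):
        V = ou_vcv(yule20, 1e-12, 2.5)
        np.testing.assert_allclose(V, 2.5 * yule20.vcv(), rtol=1e-6)

    def test_two_tip_closed_form(self):
        tree = read_tree("(A:7,B:7);")
        alpha, s2 = 0.3, 4.0
        V = ou_vcv(tree, alpha, s2)
        diag = s2 / (2 * alpha) * (1 - math.exp(-2 * alpha * 7))
        np.testing.assert_allclose(np.diag(V), diag, rtol=1e-12)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_euler_maruyama_moments(self):
        """Sample covariance of SDE simulations reproduces the analytic V."""
        tree = read_tree("((A:3,B:3):2,(C:4,D:4):1);")
        alpha, s2, theta = 0.35, 6.0, 0.0
        n_sim, dt = 40_000, 5.0 / 4000
        rng = np.random.default_rng(60)
        vals = {tree.root: np.zeros(n_sim)}  # start at theta = 0 (root state)
        for v in tree.preorder[1:]:
            x = vals[tree.parent[v]].copy()
            n_steps = int(round(tree.lengths[v] / dt))
            h = tree.lengths[v] / n_steps
            sd = math.sqrt(s2 * h)
            for _ in range(n_steps):
                x += -alpha * x * h + sd * rng.standard_normal(n_sim)
            vals[v] = x
        X = np.column_stack([vals[i] for i in range(tree.n_tips)])
        S = np.cov(X.T)
        V = ou_vcv(tree, alpha, s2)
        # elementwise MC standard errors for covariance entries
        for i in range(4):
            for j in range(4):
                se = math.sqrt((V[i, i] * V[j, j] + V[i, j] ** 2) / n_sim)
                tol = 3 * se + 0.02 * V[i, i]  # 3 SE + Euler discretization slack
                assert abs(S[i, j] - V[i, j]) < tol

    @pytest.mark.parametrize("bad", [(-0.1, 1.0), (0.5, 0.0)])
    def test_parameter_domain(self, yule20, bad):
        with pytest.raises(ValueError):
            ou_vcv(yule20, *bad)


class TestLikelihood:
    def test_matches_mvn_oracle(self):
        """lnL at arbitrary parameters equals scipy's multivariate normal density."""
        tree = read_tree("((A:2,B:2):3,(C:4,D:4):1,E:5);")
        sm = simulate_regimes(tree, build_q("ER", [0.15], 2), ("a", "b"), "a", seed=61)
        y = np.array([1.0, -0.5, 2.0, 0.3, 1.7])
        alpha, s2 = 0.4, 2.0
        m = OUModel(y, model="OUM", smap=sm)
        W, regimes = ou_weight_matrix(sm, alpha)
        theta = np.array([0.5, 1.5])
        lnl = m.loglik(alpha, s2, theta)
        oracle = stats.multivariate_normal.logpdf(
            y, mean=W @ theta, cov=ou_vcv(tree, alpha, s2)
        )
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_oum_single_regime_equals_ou1(self):
        tree = simulate_tree(25, 10.0, seed=62)
        sm = simulate_regimes(tree, np.zeros((1, 1)), ("one",), "one", seed=1)
        y = simulate_trait(sm, "OU1", 0.3, 5.0, theta=10.0, seed=63)
        f_oum = OUModel(y, model="OUM", smap=sm).fit()
        f_ou1 = OUModel(y, model="OU1", tree=tree).fit()
        assert f_oum.loglik == pytest.approx(f_ou1.loglik, abs=1e-6)

    def test_bm1_equals_ou1_alpha_zero_limit(self):
        tree = simulate_tree(25, 10.0, seed=64)
        rng = np.random.default_rng(65)
        L = np.linalg.cholesky(3.0 * tree.vcv() + 1e-10 * np.eye(25))
        y = 12.0 + L @ rng.standard_normal(25)
        f_bm = OUModel(y, model="BM1", tree=tree).fit()
        m_ou = OUModel(y, model="OU1", tree=tree)
        lnl_lim, theta, s2 = m_ou.profile_loglik(1e-12)
        assert lnl_lim == pytest.approx(f_bm.loglik, abs=1e-4)

    def test_fit_permutation_invariant(self):
        tree = simulate_tree(20, 10.0, seed=66)
        sm = simulate_regimes(tree, build_q("ER", [0.1], 2), ("a", "b"), "a", seed=67)
        y = simulate_trait(sm, "OUM", 0.3, 5.0, theta={"a": 0.0, "b": 8.0}, seed=68)
        f = OUModel(y, model="OUM", smap=sm).fit()
        # permute tips by relabeling through a rebuilt tree with same topology
        # (tip order within our arrays is fixed by construction, so permute data
        # and labels together via a pruned copy: identity here, checked via lnL)
        f2 = OUModel(y.copy(), model="OUM", smap=sm).fit()
        assert f2.loglik == pytest.approx(f.loglik, abs=1e-10)
        assert f2.theta == pytest.approx(f.theta, abs=1e-8)

    def test_location_shift_moves_theta_not_lnl(self):
        tree = simulate_tree(20, 10.0, seed=69)
        sm = simulate_regimes(tree, build_q("ER", [0.1], 2), ("a", "b"), "a", seed=70)
        y = simulate_trait(sm, "OUM", 0.3, 5.0, theta={"a": 0.0, "b": 8.0}, seed=71)
        f1 = OUModel(y, model="OUM", smap=sm).fit()
        f2 = OUModel(y + 100.0, model="OUM", smap=sm).fit()
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-5)
        assert f2.theta == pytest.approx(f1.theta + 100.0, abs=1e-3)


class TestAICc:
    def test_direct_arithmetic(self):
        assert aicc(-100.0, 3, 166) == pytest.approx(200 + 6 + 24 / 162, abs=1e-9)

    def test_equal_values_uniform_weights(self):
        np.testing.assert_allclose(aicc_weights([10.0, 10.0, 10.0]), 1 / 3)

    def test_weights_normalize(self, rng):
        w = aicc_weights(rng.uniform(100, 200, 7))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @pytest.mark.parametrize("a,expected", [(math.log(2), 1.0), (2 * math.log(2), 0.5)])
    def test_half_life(self, a, expected):
        assert half_life(a) == pytest.approx(expected)

    def test_half_life_identity_and_zero(self, rng):
        for a in rng.uniform(0.01, 5.0, 20):
            assert half_life(a) * a == pytest.approx(math.log(2), abs=1e-12)
        assert half_life(0.0) == math.inf


class TestCompareModels:
    def test_parameter_recovery_two_regimes(self):
        """Theta estimates recover generator truth on a mapped tree."""
        tree = simulate_tree(100, 20.0, seed=72)
        sm = simulate_regimes(tree, build_q("ER", [0.02], 2), ("a", "b"), "a", seed=73)
        alpha = math.log(2) / 2.0
        y = simulate_trait(sm, "OUM", alpha, 2 * alpha * 25.0,
                           theta={"a": 50.0, "b": 10.0}, seed=74)
        f = OUModel(y, model="OUM", smap=sm).fit()
        th = f.theta_dict()
        assert th["a"] == pytest.approx(50.0, abs=6.0)
        assert th["b"] == pytest.approx(10.0, abs=6.0)

    def test_dropped_map_accounting(self, mapped_tree):
        y = simulate_trait(mapped_tree, "OU1", 0.3, 5.0, theta=3.0, seed=75)
        comp = compare_models({"OUM_x": [mapped_tree] * 4}, y)
        assert comp.n_maps == 4
        assert comp.delta_aicc.min() == 0.0
        assert (comp.delta_aicc >= 0).all()
        assert comp.mean_weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert comp.per_map_weights.sum(axis=1).values == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_noiseless_limit(self):
        tree = simulate_tree(20, 10.0, seed=76)
        sm = simulate_regimes(tree, build_q("ER", [0.1], 2), ("a", "b"), "a", seed=77)
        y = simulate_trait(sm, "OUM", 1.0, 1e-8, theta={"a": 5.0, "b": 9.0}, seed=78)
        fit = OUModel(y, model="OUM", smap=sm).fit()
        ci = parametric_bootstrap(fit, n_reps=40, seed=79)
        for reg, truth in (("theta_a", 5.0), ("theta_b", 9.0)):
            row = ci.params.loc[reg]
            assert row["point"] == pytest.approx(truth, abs=1e-3)
            assert row["upper"] - row["lower"] < 0.01

    def test_bounds_ordered_and_reproducible(self):
        tree = simulate_tree(25, 10.0, seed=80)
        sm = simulate_regimes(tree, build_q("ER", [0.08], 2), ("a", "b"), "a", seed=81)
        y = simulate_trait(sm, "OUM", 0.35, 7.0, theta={"a": 0.0, "b": 10.0}, seed=82)
        fit = OUModel(y, model="OUM", smap=sm).fit()
        ci1 = parametric_bootstrap(fit, n_reps=30, seed=83)
        ci2 = parametric_bootstrap(fit, n_reps=30, seed=83)
        assert (ci1.params["lower"] <= ci1.params["upper"]).all()
        assert np.allclose(ci1.params.values, ci2.params.values)


class TestAncestralStates:
    def test_constant_trait(self, yule20):
        anc = bm_ancestral_states(yule20, np.full(yule20.n_tips, 7.5))
        np.testing.assert_allclose(anc["estimate"].values, 7.5, atol=1e-9)

    def test_root_equals_gls_mean(self, yule20, rng):
        L = np.linalg.cholesky(yule20.vcv() + 1e-10 * np.eye(20))
        y = 3.0 + L @ rng.standard_normal(20)
        anc = bm_ancestral_states(yule20, y)
        from scipy import linalg as sla

        C = yule20.vcv()
        one = np.ones(20)
        Ci1 = sla.solve(C, one)
        gls_mean = y @ Ci1 / (one @ Ci1)
        assert anc.loc[yule20.root, "estimate"] == pytest.approx(gls_mean, abs=1e-8)

    def test_three_tip_grid_oracle(self):
        """Joint-ML internal values match brute-force density maximization."""
        tree = read_tree("((A:1,B:1):1,C:2);")
        yv = np.zeros(3)
        for val, lab in zip([2.0, 0.5, -1.0], ("A", "B", "C")):
            yv[tree.tip_index(lab)] = val
        anc = bm_ancestral_states(tree, yv)

        root, inner = tree.root, [v for v in range(3, tree.n_nodes) if v != tree.root][0]

        def neg_density(u):
            vals = dict(zip((root, inner), u))
            vals.update({i: yv[i] for i in range(3)})
            s = 0.0
            for v in range(tree.n_nodes):
                if v != tree.root:
                    s += (vals[v] - vals[tree.parent[v]]) ** 2 / tree.lengths[v]
            return s

        from scipy import optimize

        res = optimize.minimize(neg_density, [0.0, 0.0])
        assert anc.loc[root, "estimate"] == pytest.approx(res.x[0], abs=1e-6)
        assert anc.loc[inner, "estimate"] == pytest.approx(res.x[1], abs=1e-6)
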