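"""Mk likelihoods, rate estimation, and stochastic character mapping."""

import itertools
import math

import numpy as np
import pytest
from scipy import linalg

from ssdevol import read_tree, simulate_tree, fit_mk, mk_loglik, sample_simmaps, summarize_maps
from ssdevol.markov import MkModel, build_q, _transition_matrices
from ssdevol.simulate import simulate_regimes


def enumeration_loglik(tree, tip_states, model):
    """Brute-force likelihood: sum over all internal-node state assignments."""
    k = model.k
    P = {v: linalg.expm(model.Q * tree.lengths[v]) for v in range(tree.n_nodes)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    tips = {tree.tip_index(lab): model.state_index(s) for lab, s in tip_states.items()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        states = dict(zip(internals, assign))
        states.update(tips)
        p = model.root_prior[states[tree.root]]
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][states[tree.parent[v]], states[v]]
        total += p
    return math.log(total)


class TestLikelihood:
    def test_zero_rate_constant_tips(self):
        tree = read_tree("(A:1,B:1);")
        model = MkModel(("a", "b"), np.zeros((2, 2)))
        ll = mk_loglik(tree, {"A": "a", "B": "a"}, model)
        assert math.exp(ll) == pytest.approx(0.5)

    def test_two_state_closed_form(self):
        """2-tip star: L = 1/2 [P_AA(t)^2 + P_BA(t)^2], P_AA = 1/2 + e^(-2qt)/2."""
        t, q = 1.5, 0.3
        tree = read_tree(f"(A:{t},B:{t});")
        model = MkModel(("a", "b"), build_q("ER", [q], 2))
        ll = mk_loglik(tree, {"A": "a", "B": "a"}, model)
        paa = 0.5 + 0.5 * math.exp(-2 * q * t)
        pba = 0.5 - 0.5 * math.exp(-2 * q * t)
        assert ll == pytest.approx(math.log(0.5 * (paa**2 + pba**2)), abs=1e-10)

    @pytest.mark.parametrize("structure", ["ER", "SYM", "ARD"])
    def test_matches_enumeration_oracle(self, structure):
        tree = simulate_tree(10, 8.0, seed=21)
        rng = np.random.default_rng(22)
        k = 3
        rates = rng.uniform(0.02, 0.2, {"ER": 1, "SYM": 3, "ARD": 6}[structure])
        model = MkModel(tuple("abc"), build_q(structure, rates, k), structure=structure)
        sm = simulate_regimes(tree, model.Q, model.alphabet, "a", seed=23)
        tip_states = sm.tip_states()
        ll = mk_loglik(tree, tip_states, model)
        assert ll == pytest.approx(enumeration_loglik(tree, tip_states, model), abs=1e-10)

    def test_relabeling_invariance(self):
        tree = simulate_tree(12, 10.0, seed=24)
        Q = build_q("ARD", np.linspace(0.01, 0.12, 6), 3)
        model = MkModel(("a", "b", "c"), Q, structure="ARD")
        sm = simulate_regimes(tree, Q, model.alphabet, "a", seed=25)
        tips = sm.tip_states()
        perm = [2, 0, 1]  # a->c, b->a, c->b positions
        Qp = Q[np.ix_(perm, perm)]
        relabel = dict(zip(("a", "b", "c"), ("x", "y", "z")))
        alpha_p = tuple(relabel[("a", "b", "c")[i]] for i in perm)
        model_p = MkModel(alpha_p, Qp, structure="ARD")
        tips_p = {lab: relabel[s] for lab, s in tips.items()}
        assert mk_loglik(tree, tips_p, model_p) == pytest.approx(
            mk_loglik(tree, tips, model), abs=1e-10
        )

    def test_unknown_state_is_error(self):
        tree = read_tree("(A:1,B:1);")
        model = MkModel(("a", "b"), build_q("ER", [0.1], 2))
        with pytest.raises(ValueError, match="alphabet"):
            mk_loglik(tree, {"A": "a", "B": "zz"}, model)

    def test_transition_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(26)
        Q = build_q("ARD", rng.uniform(0.01, 0.5, 12), 4)
        P = _transition_matrices(Q, rng.uniform(0.1, 30.0, 20))
        np.testing.assert_allclose(P.sum(axis=2), 1.0, atol=1e-10)


class TestFit:
    def test_constant_character_rate_at_bound(self):
        tree = simulate_tree(20, 10.0, seed=27)
        tips = {lab: "a" for lab in tree.tip_labels}
        fit = fit_mk(tree, tips, alphabet=("a", "b"))
        assert fit.at_bound
        assert fit.rates[0] < 1e-6

    def test_rate_recovery(self):
        """Median ML rate over replicates recovers the generating rate."""
        q_true = 0.05
        Q = build_q("ER", [q_true], 2)
        est = []
        for rep in range(12):
            tree = simulate_tree(150, 20.0, seed=100 + rep)
            sm = simulate_regimes(tree, Q, ("a", "b"), "a", seed=200 + rep)
            fit = fit_mk(tree, sm.tip_states())
            est.append(fit.rates[0])
        assert 0.03 <= np.median(est) <= 0.08

    def test_er_nested_in_ard(self):
        tree = simulate_tree(30, 15.0, seed=28)
        sm = simulate_regimes(tree, build_q("ER", [0.08], 3), ("a", "b", "c"), "a", seed=29)
        tips = sm.tip_states()
        ll_er = fit_mk(tree, tips, structure="ER").loglik
        ll_ard = fit_mk(tree, tips, structure="ARD").loglik
        assert ll_ard >= ll_er - 1e-6


class TestSampling:
    def test_near_zero_rate_no_transitions(self):
        tree = simulate_tree(15, 10.0, seed=30)
        model = MkModel(("a", "b"), build_q("ER", [1e-9], 2))
        tips = {lab: "a" for lab in tree.tip_labels}
        maps = sample_simmaps(tree, model, tips, 20, seed=31)
        assert all(m.n_transitions() == 0 for m in maps)

    def test_maps_satisfy_invariants_and_tips(self):
        tree = simulate_tree(25, 12.0, seed=32)
        sm = simulate_regimes(tree, build_q("ER", [0.1], 3), ("a", "b", "c"), "a", seed=33)
        tips = sm.tip_states()
        fit = fit_mk(tree, tips)
        maps = sample_simmaps(tree, fit.model, tips, 10, seed=34)
        for m in maps:
            m.validate()  # duration-sum + continuity invariants
            assert m.tip_states() == tips

    def test_reproducible_given_seed(self):
        tree = simulate_tree(10, 5.0, seed=35)
        sm = simulate_regimes(tree, build_q("ER", [0.2], 2), ("a", "b"), "a", seed=36)
        fit = fit_mk(tree, sm.tip_states())
        m1 = sample_simmaps(tree, fit.model, sm.tip_states(), 5, seed=77)
        m2 = sample_simmaps(tree, fit.model, sm.tip_states(), 5, seed=77)
        assert [m.segments for m in m1] == [m.segments for m in m2]


class TestSummaries:
    def test_single_regime_map(self):
        tree = simulate_tree(8, 5.0, seed=37)
        model = MkModel(("a", "b"), np.zeros((2, 2)))
        maps = sample_simmaps(tree, model, {lab: "a" for lab in tree.tip_labels}, 1, seed=1)
        s = summarize_maps(maps)
        np.testing.assert_array_equal(s.node_frequencies["a"].values, 1.0)
        assert s.mean_counts.values.sum() == 0.0

    def test_disagreeing_maps_average(self):
        tree = read_tree("(A:1,B:1);")
        from ssdevol.tree import SimmapTree

        def mk_map(root_state):
            segs = [None] * tree.n_nodes
            segs[tree.root] = [(root_state, 0.0)]
            a, b = tree.tip_index("A"), tree.tip_index("B")
            segs[a] = [(root_state, 0.5), ("a", 0.5)] if root_state != "a" else [("a", 1.0)]
            segs[b] = [(root_state, 0.5), ("b", 0.5)] if root_state != "b" else [("b", 1.0)]
            return SimmapTree(tree, segs, alphabet=("a", "b"))

        s = summarize_maps([mk_map("a"), mk_map("b")])
        assert s.node_frequencies.loc[tree.root, "a"] == pytest.approx(0.5)
        assert s.node_frequencies.loc[tree.root, "b"] == pytest.approx(0.5)

    def test_counts_match_generator_truth(self):
        """E[sampled map counts] equals E[generating history counts].

        By the law of total expectation, the mean transition count of maps
        drawn conditionally on tip states, averaged over generator
        replicates, must match the mean count of the true histories.
        Uses a fixed root prior equal to the generator's root state.
        """
        tree = simulate_tree(40, 20.0, seed=38)
        Q = build_q("ER", [0.04], 2)
        model = MkModel(("a", "b"), Q, root_prior=[1.0, 0.0])
        rng = np.random.default_rng(39)
        true_counts, sampled_means = [], []
        for rep in range(150):
            sm = simulate_regimes(tree, Q, ("a", "b"), "a", rng=rng)
            true_counts.append(sm.n_transitions())
            maps = sample_simmaps(tree, model, sm.tip_states(), 2, rng=rng)
            sampled_means.append(np.mean([m.n_transitions() for m in maps]))
        diff = np.asarray(sampled_means) - np.asarray(true_counts)
        se = diff.std(ddof=1) / math.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 0.05

    def test_different_trees_is_error(self):
        t1 = simulate_tree(8, 5.0, seed=42)
        t2 = simulate_tree(8, 5.0, seed=43)
        model = MkModel(("a",), np.zeros((1, 1)))
        m1 = sample_simmaps(t1, model, {lab: "a" for lab in t1.tip_labels}, 1, seed=1)
        m2 = sample_simmaps(t2, model, {lab: "a" for lab in t2.tip_labels}, 1, seed=1)
        with pytest.raises(ValueError, match="different trees"):
            summarize_maps(m1 + m2)
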