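"""Mk likelihood/ASR oracles, stochastic mapping, diversity through time."""

import numpy as np
import pytest

from conftest import brute_force_mk, random_binary_tree

from palmvision.mk import (
    Mk,
    MkResults,
    _build_q,
    mk_loglik,
    state_diversity_through_time,
    stationary_distribution,
    transition_matrices,
)
from palmvision.synthdata import simulate_tree_and_trait
from palmvision.trees import Phylogeny


def _random_instance(seed, max_tips=6, k=2):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_tips + 1))
    tree = random_binary_tree(n, seed)
    if k == 2:
        Q = _build_q([float(rng.uniform(0.05, 1.5))], 2, "ER")
    else:
        rates = rng.uniform(0.05, 1.0, k * (k - 1))
        Q = _build_q(rates, k, "ARD")
    states = {lab: int(rng.integers(0, k)) for lab in tree.tip_labels}
    return tree, Q, states


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        k = 2 if seed % 2 else 3
        tree, Q, states = _random_instance(seed, k=k)
        pi = np.full(k, 1.0 / k)
        expected, _ = brute_force_mk(tree, states, Q, pi)
        got = mk_loglik(tree, states, Q, root_prior="flat")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_change_limit(self):
        # two tips, both state 0, Q -> 0: likelihood -> root prior mass
        tree = Phylogeny.from_newick("(a:1.0,b:1.0);")
        Q = _build_q([1e-12], 2, "ER")
        ll = mk_loglik(tree, {"a": 0, "b": 0}, Q, root_prior="flat")
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_long_branch_limit(self):
        # ER 2-state: P(t) -> 1/2 as t -> inf
        Q = _build_q([1.0], 2, "ER")
        P = transition_matrices(Q, np.array([200.0]))[0]
        np.testing.assert_allclose(P, 0.5, atol=1e-8)

    def test_tip_order_invariance(self):
        tree, Q, states = _random_instance(3)
        ll = mk_loglik(tree, states, Q)
        shuffled = dict(reversed(list(states.items())))
        assert mk_loglik(tree, shuffled, Q) == ll

    def test_missing_tip_rejected(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        with pytest.raises(KeyError):
            mk_loglik(tree, {"a": 0}, _build_q([0.1], 2, "ER"))

    def test_invalid_q_rejected(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            mk_loglik(tree, {"a": 0, "b": 1}, np.array([[0.1, 0.1],
                                                        [0.1, -0.1]]))


class TestMarginalASR:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_conditionals(self, seed):
        k = 2 if seed % 2 else 3
        tree, Q, states = _random_instance(seed + 100, k=k)
        pi = np.full(k, 1.0 / k)
        _, marg_oracle = brute_force_mk(tree, states, Q, pi)
        model = Mk(tree, states, n_states=k, root_prior="flat")
        rates = Q[0, 1] if k == 2 else Q[~np.eye(k, dtype=bool)]
        res = MkResults(model, np.atleast_1d(rates), 0.0)
        if k == 2:
            res = MkResults(Mk(tree, states, n_states=2, constraint="ER",
                               root_prior="flat"), [Q[0, 1]], 0.0)
        else:
            res = MkResults(Mk(tree, states, n_states=3, constraint="ARD",
                               root_prior="flat"),
                            Q[~np.eye(3, dtype=bool)], 0.0)
        marg = res.marginal_asr()
        for node, probs in marg_oracle.items():
            np.testing.assert_allclose(marg.loc[node].to_numpy(), probs,
                                       atol=1e-10)

    def test_rows_sum_to_one(self):
        tree, Q, states = _random_instance(7)
        res = Mk(tree, states, constraint="ER").fit()
        marg = res.marginal_asr()
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_tips_dominated_by_shared_state(self):
        tree = random_binary_tree(8, seed=1)
        states = {lab: 0 for lab in tree.tip_labels}
        res = MkResults(Mk(tree, states, n_states=2, root_prior="flat"),
                        [0.2], 0.0)
        marg = res.marginal_asr()
        assert (marg["state_0"] > marg["state_1"]).all()


class TestFitMk:
    def test_er_rate_recovery(self):
        rates = []
        for seed in range(8):
            tree, tips = simulate_tree_and_trait(200, 1.0, 0.3,
                                                 _build_q([0.5], 2, "ER"),
                                                 seed=seed)
            res = Mk(Phylogeny.from_dendropy(tree), tips,
                     constraint="ER").fit()
            rates.append(res.rates[0])
        assert abs(np.median(rates) - 0.5) < 0.15

    def test_er_preferred_on_symmetric_data_by_aic(self):
        better = 0
        for seed in range(10):
            tree, tips = simulate_tree_and_trait(150, 1.0, 0.0,
                                                 _build_q([0.4], 2, "ER"),
                                                 seed=40 + seed)
            ph = Phylogeny.from_dendropy(tree)
            aic_er = Mk(ph, tips, constraint="ER").fit().aic
            aic_ard = Mk(ph, tips, constraint="ARD").fit().aic
            better += aic_er <= aic_ard + 4.0
        assert better >= 9

    def test_single_observed_state_flagged(self):
        tree = random_binary_tree(6, seed=2)
        states = {lab: 0 for lab in tree.tip_labels}
        res = Mk(tree, states, n_states=2).fit()
        assert any("single observed state" in f for f in res.flags)
        assert res.rates[0] < 1e-4


class TestStochasticMaps:
    @pytest.fixture
    def fitted(self):
        tree = random_binary_tree(8, seed=5, mean_branch=0.8)
        rng = np.random.default_rng(5)
        states = {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
        model = Mk(tree, states, n_states=2, constraint="ER",
                   root_prior="flat")
        return MkResults(model, [0.4], 0.0)

    def test_segments_sum_to_branch_lengths(self, fitted):
        tree = fitted.model.tree
        maps = fitted.stochastic_maps(20, seed=1)
        for smap in maps:
            for i, segs in smap.segments.items():
                assert sum(d for _, d in segs) == pytest.approx(
                    tree.lengths[i], abs=1e-9)
                # adjacent segments differ in state
                st = [s for s, _ in segs]
                assert all(a != b for a, b in zip(st, st[1:]))

    def test_endpoint_consistency(self, fitted):
        tree = fitted.model.tree
        maps = fitted.stochastic_maps(10, seed=2)
        for smap in maps:
            for i, segs in smap.segments.items():
                assert segs[0][0] == smap.node_states[tree.parent[i]]
                assert segs[-1][0] == smap.node_states[i]

    def test_seed_determinism(self, fitted):
        a = fitted.stochastic_maps(5, seed=9)
        b = fitted.stochastic_maps(5, seed=9)
        for ma, mb in zip(a, b):
            assert ma.segments == mb.segments

    def test_node_frequencies_match_marginals(self, fitted):
        n_maps = 2000
        maps = fitted.stochastic_maps(n_maps, seed=3)
        marg = fitted.marginal_asr()
        tree = fitted.model.tree
        freq = np.zeros((tree.n_nodes, 2))
        for smap in maps:
            for i in range(tree.n_nodes):
                freq[i, smap.node_states[i]] += 1
        freq /= n_maps
        for node in marg.index:
            p = marg.loc[node, "state_1"]
            se = max(np.sqrt(p * (1 - p) / n_maps), 1e-4)
            assert abs(freq[node, 1] - p) < 3.5 * se

    def test_zero_rates_give_transition_free_maps(self):
        tree = random_binary_tree(6, seed=6)
        states = {lab: 0 for lab in tree.tip_labels}
        res = MkResults(Mk(tree, states, n_states=2, root_prior="flat"),
                        [1e-12], 0.0)
        maps = res.stochastic_maps(5, seed=0)
        for smap in maps:
            for segs in smap.segments.values():
                assert len(segs) == 1


class TestDiversityThroughTime:
    def test_monomorphic_curve_equals_ltt(self):
        # ultrametric tree: lineage count climbs 2, 3, ... at node times
        dtree, states = simulate_tree_and_trait(10, 1.0, 0.0,
                                                np.zeros((2, 2)), seed=7)
        tree = Phylogeny.from_dendropy(dtree)
        states = {lab: 0 for lab in tree.tip_labels}
        res = MkResults(Mk(tree, states, n_states=2, root_prior="flat"),
                        [1e-10], 0.0)
        curve = state_diversity_through_time(res, 0, method="asr")
        np.testing.assert_allclose(curve.table.focal_diversity,
                                   curve.table.total_lineages, atol=1e-6)
        # lineages-through-time counts 2, 3, ... as nodes accumulate
        np.testing.assert_array_equal(curve.table.total_lineages,
                                      np.arange(2, 11))

    def test_state_conservation_asr(self):
        tree, Q, states = _random_instance(8, max_tips=6)
        res = MkResults(Mk(tree, states, n_states=2, constraint="ER",
                           root_prior="flat"), [Q[0, 1]], 0.0)
        c0 = state_diversity_through_time(res, 0, method="asr")
        c1 = state_diversity_through_time(res, 1, method="asr")
        total = c0.table.focal_diversity + c1.table.focal_diversity
        np.testing.assert_allclose(total, c0.table.total_lineages, atol=1e-9)

    def test_state_conservation_simulation(self):
        tree, Q, states = _random_instance(9, max_tips=6)
        res = MkResults(Mk(tree, states, n_states=2, constraint="ER",
                           root_prior="flat"), [Q[0, 1]], 0.0)
        maps = res.stochastic_maps(100, seed=4)
        c0 = state_diversity_through_time(res, 0, method="simulation",
                                          maps=maps)
        c1 = state_diversity_through_time(res, 1, method="simulation",
                                          maps=maps)
        total = c0.table.focal_diversity + c1.table.focal_diversity
        np.testing.assert_allclose(total, c0.table.total_lineages, atol=1e-9)

    def test_simulation_converges_to_asr(self):
        tree = random_binary_tree(5, seed=11, mean_branch=1.0)
        rng = np.random.default_rng(11)
        states = {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
        res = MkResults(Mk(tree, states, n_states=2, constraint="ER",
                           root_prior="flat"), [0.3], 0.0)
        asr = state_diversity_through_time(res, 1, method="asr")
        sim = state_diversity_through_time(res, 1, method="simulation",
                                           n_maps=4000, seed=12)
        np.testing.assert_allclose(sim.table.focal_diversity,
                                   asr.table.focal_diversity, atol=0.1)

    def test_unknown_focal_state_rejected(self):
        tree, Q, states = _random_instance(10)
        res = MkResults(Mk(tree, states, n_states=2), [0.1], 0.0)
        with pytest.raises(ValueError, match="focal"):
            state_diversity_through_time(res, 5, method="asr")


def test_stationary_distribution_er_is_uniform():
    Q = _build_q([0.7], 3, "ER")
    np.testing.assert_allclose(stationary_distribution(Q), 1 / 3, atol=1e-10)
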