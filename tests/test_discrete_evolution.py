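import itertools

import numpy as np
import pytest

from morphoclade.discrete_evolution import (MkFit, build_q, fit_mk,
                                            marginal_ancestral_states,
                                            mk_loglik, simmap)
from morphoclade.discrete_evolution import _transition
from morphoclade.synthetic_data import simulate_regimes, yule_tree
from morphoclade.trees import Phylogeny


def two_tip(t1=0.4, t2=0.9):
    return Phylogeny(["A", "B"], np.array([2, 2, -1]),
                     np.array([t1, t2, 0.0]))


def enumerate_loglik(tree, tips, Q, states):
    """Brute force: sum over all ancestral state assignments."""
    P = {nd: _transition(Q, tree.branch_lengths[nd])
         for nd in range(tree.n_nodes) if tree.parent[nd] >= 0}
    sidx = {s: i for i, s in enumerate(states)}
    tipidx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    internal = [nd for nd in range(tree.n_nodes) if tree.children[nd]]
    s = len(states)
    tot = 0.0
    for assign in itertools.product(range(s), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for lab, v in tips.items():
            st[tipidx[lab]] = sidx[v]
        pr = 1.0 / s
        for nd in range(tree.n_nodes):
            if tree.parent[nd] >= 0:
                pr *= P[nd][st[tree.parent[nd]], st[nd]]
        tot += pr
    return np.log(tot)


class TestMkLoglik:
    def test_two_tip_closed_form(self):
        q, t1, t2 = 0.7, 0.4, 0.9
        tree = two_tip(t1, t2)
        Q = build_q(np.array([q]), 2, "ER")
        ll = mk_loglik(tree, {"A": "x", "B": "x"}, Q, states=["x", "y"],
                       root_prior="equal")
        P1, P2 = _transition(Q, t1), _transition(Q, t2)
        lik = 0.5 * (P1[0, 0] * P2[0, 0] + P1[1, 0] * P2[1, 0])
        assert ll == pytest.approx(np.log(lik), rel=1e-10)

    def test_rate_to_zero_limit(self):
        tree = two_tip()
        Q = build_q(np.array([1e-10]), 2, "ER")
        ll = mk_loglik(tree, {"A": "x", "B": "x"}, Q, states=["x", "y"],
                       root_prior="equal")
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    @pytest.mark.parametrize("newick,structure", [
        ("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);", "ARD"),
        ("(((A:0.2,B:0.2):0.2,C:0.4):0.3,D:0.7);", "SYM"),
        ("((A:0.3,B:0.5):0.2,(C:0.4,(D:0.1,E:0.2):0.3):0.6);", "ER"),
    ])
    def test_enumeration_oracle_three_states(self, newick, structure):
        tree = Phylogeny.from_newick(newick)
        rng = np.random.default_rng(hash(newick) % 2**31)
        k = {"ER": 1, "SYM": 3, "ARD": 6}[structure]
        Q = build_q(rng.uniform(0.2, 1.0, k), 3, structure)
        states = ["s0", "s1", "s2"]
        tips = {lab: states[rng.integers(3)] for lab in tree.tip_labels}
        ll = mk_loglik(tree, tips, Q, states=states, root_prior="equal")
        assert ll == pytest.approx(enumerate_loglik(tree, tips, Q, states),
                                   rel=1e-9)

    def test_exhaustive_micro_suite_all_datasets(self):
        """5-tip tree, every 2-state tip dataset: pruning equals brute
        force enumeration."""
        tree = Phylogeny.from_newick(
            "(((A:0.2,B:0.3):0.2,C:0.4):0.3,(D:0.5,E:0.1):0.4);")
        Q = build_q(np.array([0.6, 1.1]), 2, "ARD")
        states = ["x", "y"]
        for combo in itertools.product(states, repeat=5):
            tips = dict(zip("ABCDE", combo))
            ll = mk_loglik(tree, tips, Q, states=states, root_prior="equal")
            assert ll == pytest.approx(
                enumerate_loglik(tree, tips, Q, states), rel=1e-9)

    def test_missing_tip_marginalised(self):
        tree = two_tip()
        Q = build_q(np.array([0.5]), 2, "ER")
        llm = mk_loglik(tree, {"A": "x", "B": None}, Q, states=["x", "y"],
                        root_prior="equal")
        parts = [np.exp(mk_loglik(tree, {"A": "x", "B": s}, Q,
                                  states=["x", "y"], root_prior="equal"))
                 for s in ("x", "y")]
        assert llm == pytest.approx(np.log(sum(parts)), rel=1e-9)

    def test_invalid_q_rejected(self):
        tree = two_tip()
        with pytest.raises(ValueError):
            mk_loglik(tree, {"A": "x", "B": "y"}, np.array([[1.0, 0.0],
                                                            [0.0, 1.0]]))


class TestFitMk:
    def test_er_beats_ard_on_er_data_aic(self):
        tree = yule_tree(60, seed=1).scale(2.0)
        Q = build_q(np.array([0.6]), 3, "ER")
        wins = 0
        for i in range(5):
            rm = simulate_regimes(tree, Q, ["a", "b", "c"], seed=20 + i)
            tips = {lab: rm.tip_state(lab) for lab in tree.tip_labels}
            fer = fit_mk(tree, tips, "ER", seed=0, n_starts=2)
            fard = fit_mk(tree, tips, "ARD", seed=0, n_starts=2)
            wins += fer.aic <= fard.aic
        assert wins >= 4

    def test_single_state_degenerate_warns(self, small_tree):
        tips = {lab: "only" for lab in small_tree.tip_labels}
        with pytest.warns(RuntimeWarning):
            fit = fit_mk(small_tree, tips, "ER")
        assert fit.Q[0, 1] <= 1e-6

    def test_optimum_at_least_truth(self, small_tree):
        Q = build_q(np.array([0.8]), 2, "ER")
        t = small_tree.scale(2.0)
        rm = simulate_regimes(t, Q, ["a", "b"], seed=3)
        tips = {lab: rm.tip_state(lab) for lab in t.tip_labels}
        fit = fit_mk(t, tips, "ER", seed=0)
        assert fit.loglik >= mk_loglik(t, tips, Q, states=["a", "b"]) - 1e-6

    def test_aic_bookkeeping(self, small_tree):
        t = small_tree.scale(2.0)
        rm = simulate_regimes(t, build_q(np.array([0.8]), 2, "ER"),
                              ["a", "b"], seed=4)
        tips = {lab: rm.tip_state(lab) for lab in t.tip_labels}
        for structure, k in (("ER", 1), ("SYM", 1), ("ARD", 2)):
            fit = fit_mk(t, tips, structure, seed=0)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)

    def test_aic_ranking_invariant_to_state_relabelling(self, small_tree):
        t = small_tree.scale(2.0)
        rm = simulate_regimes(t, build_q(np.array([0.8]), 2, "ER"),
                              ["a", "b"], seed=5)
        tips = {lab: rm.tip_state(lab) for lab in t.tip_labels}
        swapped = {k: {"a": "b", "b": "a"}[v] for k, v in tips.items()}
        f1 = [fit_mk(t, tips, s, seed=0).aic for s in ("ER", "ARD")]
        f2 = [fit_mk(t, swapped, s, seed=0).aic for s in ("ER", "ARD")]
        assert np.argmin(f1) == np.argmin(f2)


class TestMarginalStates:
    def test_zero_rate_all_same(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Q = build_q(np.array([1e-10]), 2, "ER")
        m = marginal_ancestral_states(tree, {k: "A" for k in "ABCD"}, Q,
                                      states=["A", "B"])
        assert np.allclose(m[:, 0], 1.0, atol=1e-6)

    def test_symmetric_root_half_half(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Q = build_q(np.array([0.5]), 2, "ER")
        m = marginal_ancestral_states(tree, {"A": "x", "B": "y", "C": "y",
                                             "D": "x"}, Q,
                                      states=["x", "y"], root_prior="equal")
        assert np.allclose(m[tree.root], [0.5, 0.5])

    def test_rows_sum_to_one(self, small_tree, two_state_map):
        tips = {lab: two_state_map.tip_state(lab)
                for lab in small_tree.tip_labels}
        Q = build_q(np.array([0.6]), 2, "ER")
        m = marginal_ancestral_states(small_tree, tips, Q,
                                      states=["deep", "shallow"])
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_matches_simmap_node_frequencies(self):
        """Marginal node probabilities agree with empirical node-state
        frequencies over many stochastic maps."""
        tree = Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        Q = build_q(np.array([0.4]), 2, "ER")
        tips = {"A": "x", "B": "x", "C": "y", "D": "y"}
        m = marginal_ancestral_states(tree, tips, Q, states=["x", "y"],
                                      root_prior="equal")
        maps = simmap(tree, tips, Q, n_maps=4000, seed=1,
                      states=["x", "y"], root_prior="equal")
        freq = np.zeros(tree.n_nodes)
        for rm in maps:
            freq += rm.node_states == 0
        freq /= len(maps)
        internal = [nd for nd in range(tree.n_nodes) if tree.children[nd]]
        se = np.sqrt(m[internal, 0] * (1 - m[internal, 0]) / len(maps))
        assert np.all(np.abs(freq[internal] - m[internal, 0])
                      <= 4 * se + 1e-3)


class TestSimmap:
    def test_zero_rate_no_changes(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Q = build_q(np.array([1e-10]), 2, "ER")
        maps = simmap(tree, {k: "A" for k in "ABCD"}, Q, n_maps=5, seed=0,
                      states=["A", "B"])
        assert all(m.n_changes() == 0 for m in maps)

    def test_single_branch_poisson_expectation(self):
        """Unconditioned changes on a branch of length t accrue at
        about rate q t for a symmetric 2-state chain."""
        q, t = 0.8, 2.0
        tree = Phylogeny(["A", "B"], np.array([2, 2, -1]),
                         np.array([t, 1e-4, 0.0]))
        Q = build_q(np.array([q]), 2, "ER")
        maps = simmap(tree, {"A": None, "B": None}, Q, n_maps=4000, seed=2,
                      states=["x", "y"], root_prior="equal")
        mean_changes = np.mean([len(m.segments[0]) - 1 for m in maps])
        expect = q * t
        se = np.sqrt(expect / len(maps))
        assert abs(mean_changes - expect) < 4 * se + 0.02

    def test_invariants_on_sampled_maps(self, small_tree, two_state_map):
        tips = {lab: two_state_map.tip_state(lab)
                for lab in small_tree.tip_labels}
        Q = build_q(np.array([0.6]), 2, "ER")
        maps = simmap(small_tree, tips, Q, n_maps=10, seed=3,
                      states=["deep", "shallow"])
        for m in maps:
            assert m.validate()
            for lab in small_tree.tip_labels:
                assert m.tip_state(lab) == tips[lab]

    def test_reproducible_per_seed_and_index(self, small_tree,
                                             two_state_map):
        tips = {lab: two_state_map.tip_state(lab)
                for lab in small_tree.tip_labels}
        Q = build_q(np.array([0.6]), 2, "ER")
        a = simmap(small_tree, tips, Q, n_maps=3, seed=9,
                   states=["deep", "shallow"])
        b = simmap(small_tree, tips, Q, n_maps=3, seed=9,
                   states=["deep", "shallow"])
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.node_states, mb.node_states)
            assert ma.segments == mb.segments

    def test_serialisation_roundtrip(self, small_tree, two_state_map):
        import json
        payload = json.loads(two_state_map.to_json())
        assert payload["states"] == ["deep", "shallow"]
        nwk = two_state_map.to_annotated_newick()
        assert "map=" in nwk
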