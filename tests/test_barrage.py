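import numpy as np
import pytest

import infinet as inf
from conftest import random_network


class TestErdosSet:
    def test_star_hub_yields_leaves(self, catalog):
        fx = catalog["out_star"]
        hub = fx.net.index_of("hub")
        result = inf.erdos_set(fx.matrices().W, [hub])
        leaves = sorted(fx.net.index_of(f"l{i}") for i in range(1, 5))
        assert result.tolist() == leaves

    def test_isolated_hub_yields_empty(self):
        net = inf.DirectedNetwork.from_named_edges(
            [("a", "b")], extra_nodes=["z"]
        )
        tm = inf.build_transition_matrices(net)
        assert inf.erdos_set(tm.W, [net.index_of("z")]).size == 0

    def test_empty_hub_rejected(self, catalog):
        with pytest.raises(ValueError):
            inf.erdos_set(catalog["out_star"].matrices().W, [])

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, 30, 90)
        tm = inf.build_transition_matrices(net)
        hub = [0, 1, 2]
        exclude = [5, 6]
        result = inf.erdos_set(tm.W, hub, exclude=exclude)
        Wd = tm.W.toarray()
        brute = sorted(
            i
            for i in range(30)
            if i not in hub and i not in exclude and np.any(Wd[i, hub] > 0)
        )
        assert result.tolist() == brute

    def test_exclusion_flag(self, catalog):
        fx = catalog["contested"]
        tm = fx.matrices()
        r, b = fx.net.index_of("r"), fx.net.index_of("b")
        with_blue = inf.erdos_set(tm.W, [r], exclude=())
        without_blue = inf.erdos_set(tm.W, [r], exclude=[b])
        assert b not in without_blue
        assert set(without_blue) <= set(with_blue)


class TestRankSingleBlue:
    def test_bottleneck_frc_matches_exact_enumeration(self):
        """frc of the bridge blocker equals the exact order-race average.

        On a down-scaled bottleneck (3-node community) the full sweep-order
        space is enumerable: the bridge survives blue only when its
        community neighbor updates first, so frc(bridge) is an order-race
        probability, strictly between 0 and the hub-appendage value 1.
        """
        from oracles import dense_sweep, enumerate_outcomes

        net = inf.DirectedNetwork.from_named_edges(
            [("hub", "leaf"), ("hub", "bridge"), ("bridge", "c1"),
             ("c1", "c2"), ("c2", "c3"), ("c3", "c1")]
        )
        tm = inf.build_transition_matrices(net)
        panel = inf.NodePanel.from_names(net, red=["hub"], blue=[])
        hub = net.index_of("hub")
        bridge = net.index_of("bridge")
        leaf = net.index_of("leaf")
        var = np.setdiff1d(np.arange(net.N), [hub])
        init = np.zeros(net.N, dtype=np.int64)
        init[hub] = 1
        init[bridge] = -1
        dist = enumerate_outcomes(tm.W.toarray(), init, var, tau_max=6)
        Wd = tm.W.toarray()
        for state in dist:  # every terminal state is an absorbing fixed point
            s = np.array(state, dtype=np.int64)
            assert dense_sweep(Wd, s, var.tolist()) == 0
        means = np.array(
            [np.mean(np.array(state)[var] == 1) for state in dist]
        )
        probs = np.array(list(dist.values()))
        exact_frc = float(means @ probs)
        exact_var = float((means**2) @ probs - exact_frc**2)
        base = inf.SimulationConfig(R=2000, tau_max=10, seed=3)
        ranking = inf.rank_single_blue([bridge, leaf], tm, panel, base)
        frc = dict(zip(ranking.candidates.tolist(), ranking.frc.tolist()))
        se = np.sqrt(exact_var / base.R)
        assert 0.0 < exact_frc < 1.0
        assert abs(frc[bridge] - exact_frc) <= 3 * se + 1e-12
        # the leaf hangs off the hub and cannot block anything
        assert frc[bridge] < frc[leaf]
        # frc sorted by Kfr is non-decreasing, by construction
        assert np.all(np.diff(ranking.frc[ranking.kfr_order]) >= 0)

    def test_disconnected_candidate_matches_baseline(self):
        net = inf.DirectedNetwork.from_named_edges(
            [("r", "a"), ("a", "b")], extra_nodes=["iso"]
        )
        tm = inf.build_transition_matrices(net)
        panel = inf.NodePanel.from_names(net, red=["r"], blue=[])
        base = inf.SimulationConfig(R=300, tau_max=10, seed=5)
        ranking = inf.rank_single_blue([net.index_of("iso")], tm, panel, base)
        baseline = inf.simulate(tm, panel, base).fr_mean
        # an isolated blue cannot influence anyone; only its own outcome
        # (always blue instead of sometimes-white) shifts the network mean
        iso_frc = ranking.frc[0]
        assert abs(iso_frc - baseline) <= 1.0 / tm.N

    def test_empty_candidates_rejected(self, catalog):
        fx = catalog["contested"]
        with pytest.raises(ValueError):
            inf.rank_single_blue(
                [], fx.matrices(), fx.panel, inf.SimulationConfig(R=5, seed=0)
            )


class TestConditionalFrc:
    def test_consistent_with_fixed_placement(self, catalog):
        """Post-hoc conditioning at n_ib=1 estimates the same frc."""
        fx = catalog["bottleneck"]
        tm = fx.matrices()
        cands = np.array(
            [fx.net.index_of("bridge"), fx.net.index_of("c3"),
             fx.net.index_of("c5"), fx.net.index_of("leaf")]
        )
        ens_cfg = inf.SimulationConfig(
            R=4000, tau_max=20, n_ib=1, candidate_set=cands, seed=8
        )
        ens = inf.simulate(tm, fx.panel, ens_cfg)
        base = inf.SimulationConfig(R=2000, tau_max=20, seed=9)
        ranking = inf.rank_single_blue(cands, tm, fx.panel, base)
        for p, c in enumerate(cands):
            cond = inf.conditional_frc(ens, int(c), min_support=100)
            assert cond.defined
            sel = [
                ens.realization_fr[r]
                for r, blues in enumerate(ens.realization_blues)
                if c in blues
            ]
            se_cond = np.std(sel) / np.sqrt(len(sel))
            se_fix = 1.0 / np.sqrt(base.R)  # conservative
            tol = 3 * np.hypot(se_cond, se_fix)
            assert abs(cond.frc_value - ranking.frc[p]) <= tol

    def test_never_drawn_query_is_undefined(self, catalog):
        fx = catalog["contested"]
        cfg = inf.SimulationConfig(R=50, tau_max=5, seed=0)  # n_ib = 0
        st = inf.simulate(fx.matrices(), fx.panel, cfg)
        out = inf.conditional_frc(st, fx.net.index_of("v3"), min_support=10)
        assert not out.defined
        assert out.support == 0

    def test_exact_vs_contains_mode(self, catalog):
        fx = catalog["contested"]
        tm = fx.matrices()
        cands = fx.panel and np.setdiff1d(
            np.arange(fx.net.N), fx.panel.pinned
        )
        cfg = inf.SimulationConfig(
            R=600, tau_max=5, n_ib=2, candidate_set=cands, seed=2
        )
        st = inf.simulate(tm, fx.panel, cfg)
        v3 = fx.net.index_of("v3")
        contains = inf.conditional_frc(st, v3, mode="contains", min_support=1)
        exact_pair = inf.conditional_frc(
            st, [v3, fx.net.index_of("v4")], mode="exact", min_support=1
        )
        assert contains.support >= exact_pair.support

    def test_support_expectation(self, catalog):
        """Support of each candidate follows the hypergeometric expectation."""
        fx = catalog["bottleneck"]
        tm = fx.matrices()
        cands = np.setdiff1d(np.arange(fx.net.N), fx.panel.pinned)[:6]
        R, n_ib = 3000, 2
        cfg = inf.SimulationConfig(
            R=R, tau_max=5, n_ib=n_ib, candidate_set=cands, seed=3
        )
        st = inf.simulate(tm, fx.panel, cfg)
        expected = R * n_ib / cands.size
        sigma = np.sqrt(R * (n_ib / cands.size) * (1 - n_ib / cands.size))
        for c in cands:
            out = inf.conditional_frc(st, int(c), min_support=1)
            assert abs(out.support - expected) <= 5 * sigma


class TestSubsetsAndGroupSelection:
    def test_subset_counts(self, catalog):
        fx = catalog["bottleneck"]
        tm = fx.matrices()
        net = fx.net
        base = inf.SimulationConfig(R=30, tau_max=10, seed=1)
        two = inf.evaluate_all_subsets(
            [net.index_of("bridge"), net.index_of("c1")], tm, fx.panel, base
        )
        assert len(two) == 4
        assert sorted(o.n_ib for o in two) == [0, 1, 1, 2]
        four_nodes = [net.index_of(x) for x in ("bridge", "c1", "c4", "leaf")]
        four = inf.evaluate_all_subsets(four_nodes, tm, fx.panel, base)
        sizes = [o.n_ib for o in four]
        assert len(four) == 16
        assert [sizes.count(k) for k in range(5)] == [1, 4, 6, 4, 1]
        baseline = [o for o in four if o.n_ib == 0][0]
        assert baseline.configuration == ()

    def test_oversize_set_rejected(self, catalog):
        fx = catalog["bottleneck"]
        with pytest.raises(ValueError):
            inf.evaluate_all_subsets(
                list(range(13)), fx.matrices(), fx.panel,
                inf.SimulationConfig(R=1, seed=0),
            )

    def test_blocking_monotone_on_bottleneck(self, catalog):
        """Adding a blocker never raises frc when all hub couplings pass
        through the evaluated nodes (small-instance check)."""
        fx = catalog["bottleneck"]
        tm = fx.matrices()
        net = fx.net
        nodes = [net.index_of("bridge"), net.index_of("leaf")]
        base = inf.SimulationConfig(R=800, tau_max=20, seed=6)
        outcomes = {
            o.configuration: o.frc_value
            for o in inf.evaluate_all_subsets(nodes, tm, fx.panel, base)
        }
        for cfg, val in outcomes.items():
            for other_cfg, other_val in outcomes.items():
                if set(cfg) < set(other_cfg):
                    assert other_val <= val + 3e-2

    def _ranking(self, candidates, frc):
        candidates = np.asarray(candidates)
        frc = np.asarray(frc, dtype=float)
        return inf.BarrageRanking(
            candidates=candidates,
            frc=frc,
            kfr_order=np.lexsort((candidates, frc)),
            support_counts=np.full(candidates.size, 100),
        )

    def test_single_ranking_returns_top_k(self):
        rk = self._ranking([10, 11, 12, 13], [0.4, 0.1, 0.3, 0.2])
        assert inf.select_optimal_group([rk], 2).tolist() == [11, 13]

    def test_identical_rankings_agree(self):
        rk = self._ranking([5, 6, 7], [0.3, 0.1, 0.2])
        one = inf.select_optimal_group([rk], 2)
        two = inf.select_optimal_group([rk, rk], 2)
        assert np.array_equal(one, two)

    def test_matches_exhaustive_rank_sum(self):
        import itertools

        rng = np.random.default_rng(17)
        cands = np.arange(8)
        rankings = [self._ranking(cands, rng.random(8)) for _ in range(3)]
        picked = inf.select_optimal_group(rankings, 3)
        pos = np.zeros(8)
        for rk in rankings:
            pos += rk.kfr_rank
        best = min(
            itertools.combinations(range(8), 3), key=lambda c: sum(pos[list(c)])
        )
        assert picked.tolist() == sorted(best)

    def test_mismatched_candidates_rejected(self):
        a = self._ranking([1, 2, 3], [0.1, 0.2, 0.3])
        b = self._ranking([1, 2, 4], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            inf.select_optimal_group([a, b], 2)
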