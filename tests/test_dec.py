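"""DEC state space, rate matrix, likelihood and ancestral splits.

The pruning likelihood is checked against an exhaustive enumeration over
every assignment of (ancestor state, cladogenetic outcome) to every
internal node — an independent oracle that shares nothing with the
implementation beyond the rate matrix definition.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import linalg as sla

import transandes as ta
from transandes.dec import (
    DECModel,
    DECParams,
    build_rate_matrix,
    branch_transition_probs,
    _cladogenetic_scenarios,
)


# -- independent oracle -----------------------------------------------------

def enumeration_likelihood(tree, tip_ranges, params, space,
                           root_constraint=None, collect_scenarios=False):
    """Brute-force tree likelihood: sum over all internal-node scenario
    assignments of the product of branch transition probabilities and
    uniform cladogenetic weights."""
    Q = build_rate_matrix(space, params)
    scen = _cladogenetic_scenarios(space)
    all_scen = []
    for S, outs in scen.items():
        w = 1.0 / len(outs)
        for l, r in outs:
            all_scen.append((S, l, r, w))
    internals = [n for n in tree.postorder_nodes() if n.child_nodes()]
    Pcache = {}

    def P(t):
        if t not in Pcache:
            Pcache[t] = sla.expm(Q * t)
        return Pcache[t]

    allowed = ([root_constraint] if root_constraint is not None
               else list(space.nonempty))
    total = 0.0
    joints = {id(n): {} for n in internals}
    for assign in itertools.product(all_scen, repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        if amap[id(tree.root)][0] not in allowed:
            continue
        prob = 1.0
        for n in internals:
            S, l, r, w = amap[id(n)]
            prob *= w
            for child, drange in zip(n.child_nodes(), (l, r)):
                if child.is_leaf():
                    bot = tip_ranges[child.taxon.label]
                    bot = frozenset(bot) if isinstance(bot, str) else bot
                else:
                    bot = amap[id(child)][0]
                prob *= P(child.edge.length)[space.index[drange],
                                             space.index[bot]]
            if prob == 0.0:
                break
        total += prob
        if collect_scenarios and prob > 0:
            for n in internals:
                S, l, r, _ = amap[id(n)]
                key = (S, l, r)
                joints[id(n)][key] = joints[id(n)].get(key, 0.0) + prob
    if collect_scenarios:
        return total, joints, internals
    return total


TIP_RANGE_SETS = {
    2: {"a": "A", "b": "B"},
    3: {"a": "A", "b": "AB", "c": "B"},
    4: {"a": "A", "b": "B", "c": "AB", "d": "A"},
    5: {"a": "B", "b": "A", "c": "A", "d": "AB", "e": "B"},
}
NEWICKS = {
    2: "(a:2,b:2);",
    3: "((a:1,b:1):1.5,c:2.5);",
    4: "((a:1,b:1):2,(c:1.5,d:1.5):1.5);",
    5: "(((a:1,b:1):1,c:2):1,(d:1.4,e:1.4):1.6);",
}


class TestStateSpace:
    def test_hub_adjacency_excludes_bc(self, hub_space):
        names = {hub_space.format_range(s) for s in hub_space.nonempty}
        assert names == {"A", "B", "C", "AB", "AC"}

    def test_two_areas_full(self, two_area_space):
        assert len(two_area_space.nonempty) == 3

    def test_three_areas_full_max3(self):
        areas = [ta.Area(c) for c in "ABC"]
        sp = ta.build_state_space(areas, 3, [("A", "B"), ("A", "C"), ("B", "C")])
        assert len(sp.nonempty) == 7

    def test_errors(self):
        areas = [ta.Area(c) for c in "AB"]
        with pytest.raises(ValueError):
            ta.build_state_space(areas, 0, [])
        with pytest.raises(ValueError):
            ta.build_state_space(areas, 2, [("A", "Z")])


class TestRateMatrix:
    def test_gain_and_loss_entries(self, two_area_space):
        Q = build_rate_matrix(two_area_space, DECParams(0.1, 0.0))
        i = two_area_space.index
        A, AB, empty = i[frozenset("A")], i[frozenset("AB")], i[frozenset()]
        assert Q[A, AB] == pytest.approx(0.1)
        assert Q[A, empty] == pytest.approx(0.0)

    def test_hub_disallows_bc(self, hub_space):
        Q = build_rate_matrix(hub_space, DECParams(0.3, 0.1))
        i = hub_space.index
        B, AB = i[frozenset("B")], i[frozenset("AB")]
        assert Q[B, AB] == pytest.approx(0.3)
        assert frozenset("BC") not in i

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_zero(self, hub_space, seed):
        rng = np.random.default_rng(seed)
        d, e = rng.uniform(0.001, 2.0, 2)
        Q = build_rate_matrix(hub_space, DECParams(d, e))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(Q[0], 0.0)  # empty state absorbing


class TestTransitionProbs:
    def test_t0_identity(self, hub_space):
        Q = build_rate_matrix(hub_space, DECParams(0.2, 0.1))
        assert np.allclose(branch_transition_probs(Q, 0.0), np.eye(len(Q)))

    def test_pure_dispersal_retention(self, two_area_space):
        d, t = 0.17, 3.5
        Q = build_rate_matrix(two_area_space, DECParams(d, 0.0))
        P = branch_transition_probs(Q, t)
        i = two_area_space.index[frozenset("A")]
        assert P[i, i] == pytest.approx(math.exp(-d * t), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_series_expansion(self, hub_space, seed):
        rng = np.random.default_rng(seed)
        Q = build_rate_matrix(hub_space,
                              DECParams(*rng.uniform(0.01, 0.3, 2)))
        t = rng.uniform(0.1, 2.0)
        # truncated-series oracle
        term = np.eye(len(Q))
        S = term.copy()
        for k in range(1, 60):
            term = term @ (Q * t) / k
            S += term
        assert np.allclose(branch_transition_probs(Q, t), S, atol=1e-10)

    def test_row_stochastic(self, hub_space, rng):
        Q = build_rate_matrix(hub_space, DECParams(0.4, 0.2))
        for t in rng.uniform(0, 30, 10):
            P = branch_transition_probs(Q, float(t))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()


class TestLikelihood:
    def test_no_rates_no_surprise(self, two_area_space):
        tree = ta.parse_newick("(a:1,b:1);")
        model = DECModel(tree, {"a": "A", "b": "A"}, two_area_space)
        nll = model.neg_loglik(DECParams(1e-12, 1e-12))
        assert nll == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n_tips", [2, 3, 4, 5])
    def test_matches_enumeration(self, n_tips, hub_space, two_area_space):
        rng = np.random.default_rng(n_tips)
        tree = ta.parse_newick(NEWICKS[n_tips])
        for space in (hub_space, two_area_space):
            for _ in range(3):
                params = DECParams(*rng.uniform(0.01, 0.6, 2))
                model = DECModel(tree, TIP_RANGE_SETS[n_tips], space)
                mine = model.neg_loglik(params)
                oracle = -math.log(enumeration_likelihood(
                    tree, TIP_RANGE_SETS[n_tips], params, space))
                assert mine == pytest.approx(oracle, rel=1e-8)

    def test_root_constraint_monotonicity(self, hub_space):
        tree = ta.parse_newick(NEWICKS[4])
        params = DECParams(0.08, 0.02)
        free = ta.tree_likelihood(tree, TIP_RANGE_SETS[4], params, hub_space)
        for constraint in ("A", "B", "AB"):
            constrained = ta.tree_likelihood(tree, TIP_RANGE_SETS[4], params,
                                             hub_space, root_constraint=constraint)
            assert constrained >= free - 1e-10

    def test_scaling_invariance(self, hub_space):
        tree = ta.parse_newick(NEWICKS[4])
        params = DECParams(0.1, 0.04)
        base = ta.tree_likelihood(tree, TIP_RANGE_SETS[4], params, hub_space)
        k = 3.7
        scaled_nwk = NEWICKS[4]
        scaled = ta.parse_newick(
            "((a:{0},b:{0}):{1},(c:{2},d:{2}):{3});".format(
                1 * k, 2 * k, 1.5 * k, 1.5 * k))
        nll = ta.tree_likelihood(scaled, TIP_RANGE_SETS[4],
                                 DECParams(0.1 / k, 0.04 / k), hub_space)
        assert nll == pytest.approx(base, rel=1e-9)

    def test_polytomy_rejected(self, hub_space):
        tree = ta.parse_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="polytom"):
            DECModel(tree, {"a": "A", "b": "A", "c": "A"}, hub_space)

    def test_unknown_tip_range_rejected(self, hub_space):
        tree = ta.parse_newick("(a:1,b:1);")
        with pytest.raises(KeyError):
            DECModel(tree, {"a": "A", "b": "BC"}, hub_space)


class TestFit:
    def test_uniform_ranges_drive_d_down(self, two_area_space):
        tree = ta.simulate_yule_tree(10, 0.4, seed=2)
        ranges = {lab: "A" for lab in tree.tip_labels}
        res = DECModel(tree, ranges, two_area_space).fit(seed=0)
        assert res.params.d < 1e-4

    def test_constrained_root_never_beats_free(self, hub_space):
        tree = ta.simulate_yule_tree(10, 0.3, seed=4)
        hist = ta.simulate_dec_history(tree, hub_space, DECParams(0.08, 0.01),
                                       "A", seed=3, condition_on_survival=True)
        free = DECModel(tree, hist.tip_ranges, hub_space).fit(seed=0)
        for constraint in ("A", "B"):
            con = DECModel(tree, hist.tip_ranges, hub_space,
                           root_constraint=constraint).fit(seed=0)
            assert con.neg_loglik >= free.neg_loglik - 1e-6

    def test_summary_mentions_rates(self, small_fit):
        text = small_fit.summary()
        assert "dispersal d" in text and "-lnL" in text


class TestAncestralSplits:
    def test_scenario_probs_sum_to_one(self, small_fit):
        recon = small_fit.ancestral_splits()
        for nid, scens in recon.node_scenarios.items():
            assert sum(s.rel_prob for s in scens) == pytest.approx(1.0)

    def test_branch_marginals_sum_to_one(self, small_fit):
        recon = small_fit.ancestral_splits()
        for marg in recon.branch_marginals.values():
            assert sum(marg.values()) == pytest.approx(1.0)

    def test_symmetric_vicariance(self, two_area_space):
        # daughters fixed in A and B on a symmetric cherry: swapping the
        # tip data mirrors the vicariance scenario probabilities exactly
        tree = ta.parse_newick("(a:2,b:2);")

        def vic_probs(tip_ranges):
            model = DECModel(tree, tip_ranges, two_area_space)
            recon = model.ancestral_splits(DECParams(0.05, 0.02))
            root_id = max(recon.node_scenarios)
            return {
                (tuple(sc.left), tuple(sc.right)): sc.rel_prob
                for sc in recon.node_scenarios[root_id]
                if sc.ancestor == frozenset("AB")
                and len(sc.left) == 1 == len(sc.right)
            }

        fwd = vic_probs({"a": "A", "b": "B"})
        rev = vic_probs({"a": "B", "b": "A"})
        assert fwd[(("A",), ("B",))] == pytest.approx(rev[(("B",), ("A",))])
        assert fwd[(("B",), ("A",))] == pytest.approx(rev[(("A",), ("B",))])

    def test_marginals_match_enumeration(self, hub_space):
        from test_dec import enumeration_likelihood  # self-import for clarity
        tree = ta.parse_newick(NEWICKS[4])
        params = DECParams(0.12, 0.03)
        model = DECModel(tree, TIP_RANGE_SETS[4], hub_space)
        recon = model.ancestral_splits(params)
        total, joints, internals = enumeration_likelihood(
            tree, TIP_RANGE_SETS[4], params, hub_space, collect_scenarios=True)
        # map oracle internals to recon node ids by tip set
        tips_of = {id(n): tuple(sorted(lf.taxon.label for lf in n.leaf_iter()))
                   for n in internals}
        recon_by_tips = {tuple(sorted(recon.node_tips[nid])): nid
                         for nid in recon.node_scenarios}
        for n in internals:
            nid = recon_by_tips[tips_of[id(n)]]
            mine = {(s.ancestor, s.left, s.right): s.rel_prob
                    for s in recon.node_scenarios[nid]}
            for key, joint in joints[id(n)].items():
                assert mine[key] == pytest.approx(joint / total, rel=1e-8)

    def test_window_retention_and_floor(self, small_fit):
        recon = small_fit.ancestral_splits(window=2.0, floor=0.1)
        for scens in recon.node_scenarios.values():
            best = max(s.loglik for s in scens)
            for s in scens:
                assert s.retained == (s.loglik >= best - 2.0)
        for nid, flagged in recon.subthreshold.items():
            for rng_ in flagged:
                assert recon.branch_marginals[nid][rng_] < 0.1
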