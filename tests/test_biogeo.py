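"""DEC rate matrix, likelihood vs enumeration, DIVA vs exhaustive search."""

import math

import numpy as np
import pytest
from scipy import linalg

import postphylo as pp
from postphylo.biogeo import cladogenetic_scenarios, range_states
from postphylo.tree import TreeError

from conftest import random_chronograms
from oracles import dec_enumerate, diva_enumerate

AREAS2 = pp.AreaSet(("X", "Y"))
AREAS3 = pp.AreaSet(("WA", "EP", "IP"))


def chrono(newick):
    return pp.Chronogram.from_phylogram(pp.parse_newick(newick))


def random_ranges(tree, areas, rng, max_range=None):
    cap = max_range or len(areas)
    out = {}
    for lab in tree.tip_labels:
        size = int(rng.integers(1, cap + 1))
        out[lab] = frozenset(rng.choice(list(areas), size=size, replace=False))
    return out


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        Q = pp.build_dec_Q(AREAS2, pp.DECParams(0.0, 0.0))
        assert np.all(Q == 0.0)

    def test_hand_construction_two_areas(self):
        Q = pp.build_dec_Q(AREAS2, pp.DECParams(1.0, 0.0))
        states = range_states(AREAS2)
        i = {s: k for k, s in enumerate(states)}
        assert Q[i[frozenset({"X"})], i[frozenset({"X", "Y"})]] == 1.0
        assert np.all(Q[i[frozenset({"X", "Y"})]] == 0.0)  # no e, nothing to gain

    def test_state_count_three_areas(self):
        assert len(range_states(AREAS3)) == 8  # 7 non-empty + empty

    def test_rows_sum_to_zero_and_expm_stochastic(self):
        Q = pp.build_dec_Q(AREAS3, pp.DECParams(0.37, 0.12))
        assert np.abs(Q.sum(axis=1)).max() <= 1e-12
        for t in (0.0, 0.5, 7.0, 100.0):
            P = linalg.expm(Q * t)
            assert np.abs(P.sum(axis=1) - 1.0).max() <= 1e-10

    def test_multipliers_scale_dispersal(self):
        mult = ((0.0, 0.5), (2.0, 0.0))
        Q = pp.build_dec_Q(AREAS2, pp.DECParams(1.0, 0.0, multipliers=mult))
        states = range_states(AREAS2)
        i = {s: k for k, s in enumerate(states)}
        assert Q[i[frozenset({"X"})], i[frozenset({"X", "Y"})]] == 0.5
        assert Q[i[frozenset({"Y"})], i[frozenset({"X", "Y"})]] == 2.0

    def test_max_range_caps_states(self):
        assert len(range_states(AREAS3, max_range=1)) == 4  # 3 singletons + empty


class TestScenarios:
    def test_single_area_identity(self):
        r = frozenset({"WA"})
        assert cladogenetic_scenarios(r) == [(r, r)]

    def test_two_area_count(self):
        # 4 subset-sympatry + 2 vicariance ordered pairs
        assert len(cladogenetic_scenarios(frozenset({"WA", "EP"}))) == 6

    def test_three_area_daughters_valid(self):
        r = frozenset({"WA", "EP", "IP"})
        for s1, s2 in cladogenetic_scenarios(r):
            assert s1 and s2
            assert s1 | s2 == r
            assert min(len(s1), len(s2)) == 1


class TestDecLoglik:
    def test_no_events_flat_prior(self):
        t = chrono("((A:1,B:1):1,C:2);")
        ranges = {lab: frozenset({"X"}) for lab in "ABC"}
        ll = pp.dec_loglik(t, ranges, pp.DECParams(0.0, 0.0), AREAS2)
        assert ll == pytest.approx(math.log(1.0 / 3.0), abs=1e-12)

    def test_two_tip_matches_enumeration(self):
        rng = np.random.default_rng(81)
        t = chrono("(A:0.7,B:0.7);")
        for _ in range(10):
            d, e = float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.0, 0.5))
            ranges = random_ranges(t, AREAS2, rng)
            got = pp.dec_loglik(t, ranges, pp.DECParams(d, e), AREAS2)
            want, _ = dec_enumerate(t, ranges, list(AREAS2), d, e)
            assert got == pytest.approx(want, abs=1e-8)

    def test_three_tip_three_area_matches_enumeration(self):
        rng = np.random.default_rng(82)
        for rep in range(8):
            tree = pp.simulate_yule(3, 1.0, seed=int(rng.integers(2**31)))
            d, e = float(rng.uniform(0.05, 0.8)), float(rng.uniform(0.0, 0.3))
            ranges = random_ranges(tree, AREAS3, rng)
            got = pp.dec_loglik(tree, ranges, pp.DECParams(d, e), AREAS3)
            want, _ = dec_enumerate(tree, ranges, list(AREAS3), d, e)
            assert got == pytest.approx(want, abs=1e-8)

    def test_extinction_monotonicity(self):
        """Single-area tips on long branches: more extinction, worse fit."""
        t = chrono("((A:4,B:4):4,C:8);")
        ranges = {lab: frozenset({"WA"}) for lab in "ABC"}
        lls = [
            pp.dec_loglik(t, ranges, pp.DECParams(0.1, e), AREAS3)
            for e in (0.0, 0.1, 0.3, 0.6)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_polytomy_rejected(self):
        t = chrono("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="bifurcating"):
            pp.dec_loglik(t, {lab: frozenset({"X"}) for lab in "ABC"},
                          pp.DECParams(0.1, 0.1), AREAS2)


class TestFitDec:
    def test_identical_single_area_extinction_at_floor(self):
        tree = pp.simulate_yule(12, 1.0, seed=83)
        ranges = {lab: frozenset({"WA"}) for lab in tree.tip_labels}
        params, _ = pp.fit_dec(tree, ranges, AREAS3)
        assert params.e <= 1e-6

    def test_fit_beats_generating_params(self):
        tree = pp.simulate_yule(40, 1.0, seed=84)
        true = pp.DECParams(0.3, 0.05)
        ranges = pp.simulate_dec_ranges(tree, true, AREAS3, {"EP"}, seed=85)
        fitted, ll = pp.fit_dec(tree, ranges, AREAS3)
        assert ll >= pp.dec_loglik(tree, ranges, true, AREAS3) - 1e-6


class TestDecAncestral:
    def test_deterministic_single_area(self):
        t = chrono("((A:1,B:1):1,C:2);")
        ranges = {lab: frozenset({"X"}) for lab in "ABC"}
        marg = pp.dec_ancestral_ranges(t, ranges, pp.DECParams(0.0, 0.0), AREAS2)
        for dist in marg.values():
            assert dist[frozenset({"X"})] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(86)
        for rep in range(6):
            tree = pp.simulate_yule(3, 1.0, seed=int(rng.integers(2**31)))
            d, e = float(rng.uniform(0.05, 0.8)), float(rng.uniform(0.0, 0.3))
            ranges = random_ranges(tree, AREAS3, rng)
            got = pp.dec_ancestral_ranges(tree, ranges, pp.DECParams(d, e), AREAS3)
            _, want = dec_enumerate(tree, ranges, list(AREAS3), d, e)
            for idx, dist in want.items():
                for r, prob in dist.items():
                    assert got[idx].get(r, 0.0) == pytest.approx(prob, abs=1e-8)
            for dist in got.values():
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-10)

    def test_area_relabeling_permutes(self):
        t = chrono("((A:1,B:1):1,C:2);")
        params = pp.DECParams(0.2, 0.05)
        r1 = {"A": frozenset({"WA"}), "B": frozenset({"EP"}), "C": frozenset({"EP"})}
        r2 = {"A": frozenset({"EP"}), "B": frozenset({"WA"}), "C": frozenset({"WA"})}
        m1 = pp.dec_ancestral_ranges(t, r1, params, AREAS3)
        m2 = pp.dec_ancestral_ranges(t, r2, params, AREAS3)
        swap = {"WA": "EP", "EP": "WA", "IP": "IP"}
        for idx in m1:
            for r, prob in m1[idx].items():
                mapped = frozenset(swap[a] for a in r)
                assert m2[idx].get(mapped, 0.0) == pytest.approx(prob, abs=1e-10)


class TestDiva:
    def test_worked_example(self):
        t = pp.parse_newick("((A:1,B:1):1,C:2);")
        ranges = {"A": frozenset({"WA"}), "B": frozenset({"EP"}),
                  "C": frozenset({"EP"})}
        cost, opt = pp.diva_parsimony(t, ranges)
        assert cost == 1
        ab = t.mrca({"A", "B"})
        assert frozenset({"WA", "EP"}) in opt[ab.index]

    def test_uniform_tips_cost_zero(self):
        t = pp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ranges = {lab: frozenset({"IP"}) for lab in "ABCD"}
        cost, opt = pp.diva_parsimony(t, ranges, areas=AREAS3)
        assert cost == 0
        for node in t.nodes:
            if not node.is_tip:
                assert opt[node.index] == {frozenset({"IP"})}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(87)
        for rep in range(12):
            n = int(rng.integers(3, 7))
            tree = pp.simulate_yule(n, 1.0, seed=int(rng.integers(2**31)))
            ranges = random_ranges(tree, AREAS3, rng, max_range=2)
            cost, opt = pp.diva_parsimony(tree, ranges, areas=AREAS3)
            want_cost, want_opt = diva_enumerate(tree, ranges, list(AREAS3))
            assert cost == want_cost
            for node in tree.nodes:
                if not node.is_tip:
                    assert opt[node.index] == want_opt[node.index]

    def test_area_relabeling_invariance(self):
        tree = pp.simulate_yule(6, 1.0, seed=88)
        rng = np.random.default_rng(89)
        ranges = random_ranges(tree, AREAS3, rng, max_range=2)
        swap = {"WA": "IP", "IP": "WA", "EP": "EP"}
        swapped = {lab: frozenset(swap[a] for a in r) for lab, r in ranges.items()}
        c1, _ = pp.diva_parsimony(tree, ranges, areas=AREAS3)
        c2, _ = pp.diva_parsimony(tree, swapped, areas=AREAS3)
        assert c1 == c2


class TestMaxRangeOneReduction:
    def test_equals_direct_single_area_chain(self):
        """max_range=1, e=0: no anagenetic moves remain, so the DEC
        likelihood equals a direct per-area chain with zero rates."""
        tree = pp.simulate_yule(5, 1.0, seed=90)
        labels = sorted(tree.tip_labels)
        ranges = {lab: frozenset({"WA"}) for lab in labels}
        params = pp.DECParams(0.4, 0.0, max_range=1)
        got = pp.dec_loglik(tree, ranges, params, AREAS3)
        # direct: identical inheritance everywhere, flat root prior over
        # the 3 singleton states, and the data force a single state
        assert got == pytest.approx(math.log(1.0 / 3.0), abs=1e-10)
        mixed = dict(ranges)
        mixed[labels[0]] = frozenset({"EP"})
        assert pp.dec_loglik(tree, mixed, params, AREAS3) == -math.inf


class TestPosteriorSummary:
    def test_identical_trees_match_single_tree(self):
        base = pp.simulate_yule(6, 1.0, seed=91)
        rng = np.random.default_rng(92)
        ranges = random_ranges(base, AREAS3, rng, max_range=2)
        sample = pp.emulate_posterior(base, 10, 0.0, seed=93)
        params = pp.DECParams(0.2, 0.05)
        summary = pp.posterior_range_summary(
            sample, ranges, "DEC", n_trees=10, seed=0, areas=AREAS3,
            dec_params=params)
        single = pp.dec_ancestral_ranges(base, ranges, params, AREAS3)
        clades = base.clade_sets()
        for idx, dist in single.items():
            top = max(dist, key=dist.get)
            info = summary[clades[idx]]
            assert info["presence"] == 1.0
            assert info["ranges"][top] == pytest.approx(1.0)

    def test_full_sample_no_subsampling_variance(self):
        base = pp.simulate_yule(5, 1.0, seed=94)
        rng = np.random.default_rng(95)
        ranges = random_ranges(base, AREAS3, rng, max_range=1)
        sample = pp.emulate_posterior(base, 8, 0.05, seed=96)
        a = pp.posterior_range_summary(sample, ranges, "DIVA", n_trees=8,
                                       seed=1, areas=AREAS3)
        b = pp.posterior_range_summary(sample, ranges, "DIVA", n_trees=8,
                                       seed=999, areas=AREAS3)
        assert a == b

    def test_clade_presence_bookkeeping(self):
        """A clade present in k of the drawn trees is evaluated k times."""
        base = pp.simulate_yule(6, 1.0, seed=97)
        sample = pp.emulate_posterior(base, 20, 0.1, topology_swap_rate=1.5,
                                      seed=98)
        rng = np.random.default_rng(99)
        ranges = random_ranges(base, AREAS3, rng, max_range=1)
        summary = pp.posterior_range_summary(
            sample, ranges, "DIVA", n_trees=20, seed=2, areas=AREAS3,
            min_clade_fraction=0.0)
        counts = {}
        for tree in sample:
            for n, clade in tree.clade_sets().items():
                if not tree.nodes[n].is_tip:
                    counts[clade] = counts.get(clade, 0) + 1
        for clade, k in counts.items():
            assert summary[clade]["presence"] == pytest.approx(k / 20)
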