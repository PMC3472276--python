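"""Paired tMRCA extraction, older-than fractions and ln Bayes factors."""

import math

import numpy as np
import pytest
from scipy import stats

import postphylo as pp
from postphylo.tree import Node, TreeError


def chrono(newick):
    return pp.Chronogram.from_phylogram(pp.parse_newick(newick))


def two_cherry_sample(ages_ab, ages_cd, root_pad=5.0):
    """Trees ((a1,a2),(c1,c2)) with prescribed per-tree cherry ages."""
    trees = []
    for x, y in zip(ages_ab, ages_cd):
        root = Node()
        root.age = max(x, y) + root_pad
        left = root.add_child(Node())
        left.age = x
        right = root.add_child(Node())
        right.age = y
        for lab in ("a1", "a2"):
            tip = left.add_child(Node(lab))
            tip.age = 0.0
        for lab in ("c1", "c2"):
            tip = right.add_child(Node(lab))
            tip.age = 0.0
        trees.append(pp.Chronogram.from_ages(root))
    return pp.TreeSample(trees)


PAIR_A = pp.GeminatePair("pairA", frozenset({"a1"}), frozenset({"a2"}))
PAIR_C = pp.GeminatePair("pairC", frozenset({"c1"}), frozenset({"c2"}))


class TestExtract:
    def test_single_tree(self):
        sample = pp.TreeSample([chrono("((A:1,B:1):1,C:2);")])
        pair = pp.GeminatePair("p", frozenset({"A"}), frozenset({"B"}))
        assert pp.extract_tmrca_samples(sample, pair).tolist() == [1.0]

    def test_length_and_order(self):
        ages = [1.0, 2.0, 3.0]
        sample = two_cherry_sample(ages, [4.0, 4.0, 4.0])
        got = pp.extract_tmrca_samples(sample, PAIR_A)
        assert got.tolist() == ages

    def test_mean_tracks_generating_age(self):
        # base tree with well-separated node ages, so the ordering
        # rejection in the jitter is essentially never triggered and the
        # lognormal moment formula applies exactly
        base = two_cherry_sample([1.0], [2.0])[0]
        sample = pp.emulate_posterior(base, 400, 0.1, seed=52)
        ages = pp.extract_tmrca_samples(sample, PAIR_A)
        mu = 1.0 * math.exp(0.1**2 / 2)
        assert abs(ages.mean() - mu) <= 2 * ages.std() / math.sqrt(len(ages))

    def test_missing_tip_names_tree_index(self):
        sample = two_cherry_sample([1.0], [2.0])
        bad = pp.GeminatePair("p", frozenset({"a1"}), frozenset({"zz"}))
        with pytest.raises(TreeError, match="tree 0"):
            pp.extract_tmrca_samples(sample, bad)


class TestAsynchronyFraction:
    def test_hand_count(self):
        assert pp.asynchrony_fraction([3, 2, 5], [1, 4, 2]) == pytest.approx(2 / 3)

    def test_all_ties_half(self):
        assert pp.asynchrony_fraction([1.0, 2.0], [1.0, 2.0]) == 0.5

    def test_antisymmetry(self):
        rng = np.random.default_rng(60)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert pp.asynchrony_fraction(a, b) == pytest.approx(
            1.0 - pp.asynchrony_fraction(b, a)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pp.asynchrony_fraction([1.0], [1.0, 2.0])

    def test_pairing_matters(self):
        """Correlated age vectors: breaking the pairing changes p."""
        rng = np.random.default_rng(61)
        shared = rng.normal(5.0, 2.0, size=2000)
        a = shared + 0.3 + rng.normal(0, 0.05, size=2000)
        b = shared + rng.normal(0, 0.05, size=2000)
        paired = pp.asynchrony_fraction(a, b)
        shuffled = pp.asynchrony_fraction(a, np.sort(b))
        assert paired > 0.99
        assert abs(shuffled - paired) > 0.2


class TestLnBayesFactor:
    def test_even_odds_zero(self):
        assert pp.ln_bayes_factor(0.5) == pytest.approx(0.0, abs=1e-15)

    def test_direct_evaluations(self):
        assert pp.ln_bayes_factor(0.69) == pytest.approx(math.log(0.69 / 0.31), abs=1e-9)
        assert pp.ln_bayes_factor(0.98) == pytest.approx(math.log(49.0), abs=1e-9)

    def test_antisymmetry(self):
        for p in (0.1, 0.31, 0.69, 0.9):
            assert pp.ln_bayes_factor(p) == pytest.approx(
                -pp.ln_bayes_factor(1.0 - p), abs=1e-12
            )

    def test_prior_odds_shift(self):
        assert pp.ln_bayes_factor(0.69, prior_odds=2.0) == pytest.approx(
            math.log(0.69 / 0.31) - math.log(2.0)
        )

    def test_boundary_rejected_with_advice(self):
        with pytest.raises(ValueError, match="resolvable"):
            pp.ln_bayes_factor(1.0)


class TestGeminateReport:
    def test_constant_offset_gives_boundary(self):
        rng = np.random.default_rng(70)
        base = rng.uniform(2.0, 4.0, size=50)
        sample = two_cherry_sample(base + 1.0, base)
        result = pp.geminate_report(sample, [PAIR_A, PAIR_C], seed=1)
        (comp,) = result.comparisons
        assert comp.p_a_older == 1.0
        assert comp.ln_bf == math.inf
        assert comp.ln_bf_bound == pytest.approx(math.log(99.0 / 1.0), rel=0.02)

    def test_normal_offset_closed_form(self):
        """Independent N(5,1) vs N(4,1) ages: P(X>Y) = Phi(1/sqrt(2))."""
        rng = np.random.default_rng(71)
        n = 10000
        x = np.clip(rng.normal(5.0, 1.0, size=n), 0.05, None)
        y = np.clip(rng.normal(4.0, 1.0, size=n), 0.05, None)
        sample = two_cherry_sample(x, y, root_pad=10.0)
        result = pp.geminate_report(sample, [PAIR_A, PAIR_C], seed=2)
        (comp,) = result.comparisons
        assert comp.p_a_older == pytest.approx(
            stats.norm.cdf(1.0 / math.sqrt(2.0)), abs=0.03
        )

    def test_three_pairs_three_comparisons(self):
        rng = np.random.default_rng(72)
        n = 30
        trees = []
        for _ in range(n):
            root = Node()
            root.age = 20.0
            mid = root.add_child(Node())
            mid.age = 15.0
            c3 = root.add_child(Node())
            c3.age = float(rng.uniform(1, 3))
            for lab in ("e1", "e2"):
                t = c3.add_child(Node(lab)); t.age = 0.0
            c1 = mid.add_child(Node())
            c1.age = float(rng.uniform(1, 3))
            for lab in ("a1", "a2"):
                t = c1.add_child(Node(lab)); t.age = 0.0
            c2 = mid.add_child(Node())
            c2.age = float(rng.uniform(1, 3))
            for lab in ("c1", "c2"):
                t = c2.add_child(Node(lab)); t.age = 0.0
            trees.append(pp.Chronogram.from_ages(root))
        sample = pp.TreeSample(trees)
        pairs = [
            PAIR_A, PAIR_C,
            pp.GeminatePair("pairE", frozenset({"e1"}), frozenset({"e2"})),
        ]
        result = pp.geminate_report(sample, pairs, seed=3)
        assert len(result.comparisons) == 3
        assert set(result.plot_sample) == {"pairA", "pairC", "pairE"}
        assert all(len(v) == 30 for v in result.plot_sample.values())
        for name, (lo, hi) in result.hpd.items():
            assert lo <= hi

    def test_configured_ordering_recovered(self):
        """Distinct generating offsets come back in the configured order."""
        rng = np.random.default_rng(73)
        n = 500
        x = rng.lognormal(math.log(3.0), 0.1, size=n)
        y = rng.lognormal(math.log(2.0), 0.1, size=n)
        sample = two_cherry_sample(x, y)
        result = pp.geminate_report(sample, [PAIR_A, PAIR_C], seed=4)
        (comp,) = result.comparisons
        assert comp.p_a_older > 0.95
        assert comp.ln_bf > math.log(19.0) or comp.ln_bf == math.inf

    def test_single_pair_rejected(self):
        sample = two_cherry_sample([1.0], [2.0])
        with pytest.raises(ValueError, match="2 geminate pairs"):
            pp.geminate_report(sample, [PAIR_A], seed=0)
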