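"""Mk likelihood vs enumeration, ER/ARD fitting, LRT, ancestral marginals."""

import math

import numpy as np
import pytest

import postphylo as pp
from postphylo.mk import (
    MkModel,
    _Pruner,
    _loglik_scalar,
    fit_mk,
    fit_mk_batch,
    tip_order_of,
    transition_matrix,
)
from postphylo.tree import TreeError

from conftest import random_chronograms
from oracles import expm_series, mk_enumerate


def chrono(newick):
    return pp.Chronogram.from_phylogram(pp.parse_newick(newick))


def random_trait(tree, rng):
    states = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
    if len(set(states.values())) == 1:  # keep instances informative
        first = sorted(states)[0]
        states[first] = 1 - states[first]
    return states


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        P = transition_matrix(MkModel(3.0, 0.5), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_er_stationary_limit(self):
        P = transition_matrix(MkModel(1.0, 1.0, "ER"), 1e3)
        assert np.allclose(P, 0.25 + np.zeros((2, 2)) + 0.25)

    def test_matches_series_oracle(self):
        m = MkModel(2.0, 1.0)
        Q = np.array([[-2.0, 2.0], [1.0, -1.0]])
        P = transition_matrix(m, 0.3)
        assert np.abs(P - expm_series(Q, 0.3)).max() <= 1e-10
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkModel(1.0, 1.0), -0.1)


class TestLoglik:
    def test_cherry_no_change(self):
        """Rates 0: only the root prior contributes."""
        t = chrono("(A:1,B:1);")
        ll = pp.mk_loglik(t, {"A": 0, "B": 0}, MkModel(0.0, 0.0))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_cherry_independence_limit(self):
        t = chrono("(A:200,B:200);")
        ll = pp.mk_loglik(t, {"A": 0, "B": 1}, MkModel(1.0, 1.0, "ER"))
        assert ll == pytest.approx(math.log(0.25), abs=1e-9)

    def test_missing_tip_state_rejected(self, three_tip_chrono):
        with pytest.raises(TreeError, match="C"):
            pp.mk_loglik(three_tip_chrono, {"A": 0, "B": 1}, MkModel(1, 1))

    def test_matches_enumeration_oracle(self):
        """Pruning equals the sum over all internal-state assignments."""
        rng = np.random.default_rng(17)
        for tree in random_chronograms(120, 4, 8, seed=18):
            trait = random_trait(tree, rng)
            model = MkModel(float(rng.lognormal(0, 1)), float(rng.lognormal(0, 1)))
            got = pp.mk_loglik(tree, trait, model)
            want, _ = mk_enumerate(tree, trait, model)
            assert abs(got - want) <= 1e-10

    def test_zero_length_cherry_collapses(self):
        """A cherry on zero-length edges behaves as a single observation."""
        with_cherry = chrono("((A:0,B:0):2,C:2);")
        collapsed = chrono("(AB:2,C:2);")
        m = MkModel(0.7, 1.3)
        ll1 = pp.mk_loglik(with_cherry, {"A": 1, "B": 1, "C": 0}, m)
        ll2 = pp.mk_loglik(collapsed, {"AB": 1, "C": 0}, m)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_relabeling_symmetry(self, yule20):
        rng = np.random.default_rng(19)
        trait = random_trait(yule20, rng)
        flipped = {k: 1 - v for k, v in trait.items()}
        m = MkModel(0.4, 1.7, root_prior=(0.3, 0.7))
        m_swap = MkModel(1.7, 0.4, root_prior=(0.7, 0.3))
        assert pp.mk_loglik(yule20, trait, m) == pytest.approx(
            pp.mk_loglik(yule20, flipped, m_swap), abs=1e-10
        )

    def test_batch_matches_scalar(self, yule20):
        rng = np.random.default_rng(20)
        order = tip_order_of(yule20)
        traits = np.array(
            [[random_trait(yule20, rng)[lab] for lab in order] for _ in range(5)]
        )
        lls = pp.mk_loglik_batch(yule20, traits, 0.8, 1.4)
        for i in range(5):
            trait = {lab: int(traits[i, j]) for j, lab in enumerate(order)}
            assert lls[i] == pytest.approx(
                pp.mk_loglik(yule20, trait, MkModel(0.8, 1.4)), abs=1e-10
            )


class TestFit:
    def test_constant_trait_boundary(self, yule20):
        trait = {lab: 0 for lab in yule20.tip_labels}
        with pytest.warns(UserWarning, match="constant"):
            model, ll = fit_mk(yule20, trait, "ER")
        assert model.q01 <= 1e-6
        assert ll == pytest.approx(math.log(0.5), abs=1e-4)

    def test_ard_never_below_er(self):
        rng = np.random.default_rng(23)
        for tree in random_chronograms(5, 10, 25, seed=24):
            trait = random_trait(tree, rng)
            _, ll_er = fit_mk(tree, trait, "ER")
            _, ll_ard = fit_mk(tree, trait, "ARD")
            assert ll_ard >= ll_er - 1e-9

    def test_fit_beats_grid(self, yule20):
        rng = np.random.default_rng(25)
        trait = random_trait(yule20, rng)
        model, ll = fit_mk(yule20, trait, "ARD")
        for q01 in (0.01, 0.1, 1.0, 10.0):
            for q10 in (0.01, 0.1, 1.0, 10.0):
                assert ll >= pp.mk_loglik(yule20, trait, MkModel(q01, q10)) - 1e-8

    def test_fit_recovers_generating_rate(self):
        tree = pp.simulate_yule(200, 1.0, seed=26)
        trait = pp.simulate_mk_trait(tree, MkModel(1.0, 1.0, "ER"), seed=27)
        model, ll = fit_mk(tree, trait, "ER")
        assert ll >= pp.mk_loglik(tree, trait, MkModel(1.0, 1.0, "ER")) - 1e-9
        assert 0.2 < model.q01 < 5.0

    def test_batch_fit_matches_scalar_fit(self):
        tree = pp.simulate_yule(60, 1.0, seed=28)
        order = tip_order_of(tree)
        rng = np.random.default_rng(29)
        traits = np.array(
            [[random_trait(tree, rng)[lab] for lab in order] for _ in range(4)]
        )
        q01b, q10b, llb = fit_mk_batch(tree, traits, "ARD")
        _, _, ller = fit_mk_batch(tree, traits, "ER")
        for i in range(4):
            trait = {lab: int(traits[i, j]) for j, lab in enumerate(order)}
            _, ll_er = fit_mk(tree, trait, "ER")
            _, ll_ard = fit_mk(tree, trait, "ARD")
            assert ller[i] == pytest.approx(ll_er, abs=1e-6)
            assert llb[i] == pytest.approx(ll_ard, abs=2e-3)
            assert llb[i] >= ller[i] - 1e-9


class TestLrt:
    def test_chi2_tail_example(self):
        d, p = pp.lrt_pvalue(-10.0, -8.0, df=1)
        assert d == pytest.approx(4.0)
        assert p == pytest.approx(0.04550, abs=5e-6)

    def test_equal_logliks(self):
        d, p = pp.lrt_pvalue(-5.0, -5.0)
        assert d == 0.0 and p == 1.0

    def test_tiny_negative_clamped(self):
        d, p = pp.lrt_pvalue(-5.0, -5.0 - 1e-12)
        assert d == 0.0 and p == 1.0

    def test_misordered_rejected(self):
        with pytest.raises(ValueError):
            pp.lrt_pvalue(-5.0, -6.0)
        with pytest.raises(ValueError):
            pp.lrt_pvalue(-5.0, -4.0, df=0)


class TestMarginals:
    def test_symmetric_cherry_root_uniform(self):
        t = chrono("(A:1,B:1);")
        marg = pp.marginal_ancestral_states(t, {"A": 0, "B": 1}, MkModel(1, 1, "ER"))
        root = marg[t.root.index]
        assert root[0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_rates_propagate_tip_state(self):
        t = chrono("((A:1,B:1):1,(C:1,D:1):1);")
        trait = {lab: 0 for lab in "ABCD"}
        marg = pp.marginal_ancestral_states(t, trait, MkModel(0.0, 0.0))
        for p0, p1 in marg.values():
            assert p0 == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for tree in random_chronograms(60, 4, 8, seed=32):
            trait = random_trait(tree, rng)
            model = MkModel(float(rng.lognormal(0, 1)), float(rng.lognormal(0, 1)))
            got = pp.marginal_ancestral_states(tree, trait, model)
            _, want = mk_enumerate(tree, trait, model)
            for idx, pair in want.items():
                assert got[idx][0] == pytest.approx(pair[0], abs=1e-10)
                assert got[idx][1] == pytest.approx(pair[1], abs=1e-10)
            for p0, p1 in got.values():
                assert p0 + p1 == pytest.approx(1.0, abs=1e-10)

    def test_relabeling_mirrors_marginals(self, yule20):
        rng = np.random.default_rng(33)
        trait = random_trait(yule20, rng)
        flipped = {k: 1 - v for k, v in trait.items()}
        m = MkModel(0.4, 1.7)
        m_swap = MkModel(1.7, 0.4)
        a = pp.marginal_ancestral_states(yule20, trait, m)
        b = pp.marginal_ancestral_states(yule20, flipped, m_swap)
        for idx in a:
            assert a[idx][0] == pytest.approx(b[idx][1], abs=1e-10)
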