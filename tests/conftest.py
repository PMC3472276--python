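"""Shared fixtures: small hand-built trees and seeded random instances."""

from __future__ import annotations

import numpy as np
import pytest

import postphylo as pp


@pytest.fixture
def three_tip_chrono() -> pp.Chronogram:
    """((A:1,B:1):1,C:2); — the canonical worked example tree."""
    return pp.Chronogram.from_phylogram(pp.parse_newick("((A:1,B:1):1,C:2);"))


@pytest.fixture
def yule20() -> pp.Chronogram:
    return pp.simulate_yule(20, 1.0, seed=42)


def random_chronograms(n_trees: int, tips_lo: int, tips_hi: int, seed: int):
    """Seeded stream of small Yule chronograms of varying size."""
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        n = int(rng.integers(tips_lo, tips_hi + 1))
        yield pp.simulate_yule(n, 1.0, seed=int(rng.integers(2**31)))
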