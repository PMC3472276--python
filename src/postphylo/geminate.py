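"""Divergence-asynchrony test for geminate species pairs.

Geminate pairs are sister species separated by the rise of the Isthmus
of Panama — one member in the eastern Pacific, one in the western
Atlantic.  If the isthmus split them all simultaneously, their
divergence node ages should coincide.  The test works directly on a
posterior sample of chronograms: for each pair the age of the most
recent common ancestor (tMRCA) of its two members is extracted from
every tree, and for each ordered pair of pairs the fraction ``p`` of
trees in which one node is older than the other is converted to a
natural-log Bayes factor ``ln(p / (1 - p))`` (prior odds 1: a priori
either node is equally likely to be the older one).

The per-tree pairing is essential: node ages within one posterior tree
are strongly correlated, and the paired fraction uses exactly that
correlation.  Age vectors are therefore never sorted or shuffled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .posterior import TreeSample, hpd_interval
from .tree import TreeError

__all__ = [
    "GeminatePair",
    "PairComparison",
    "AsynchronyResult",
    "extract_tmrca_samples",
    "asynchrony_fraction",
    "ln_bayes_factor",
    "geminate_report",
    "read_pairs_config",
]


@dataclass(frozen=True)
class GeminatePair:
    """A named divergence node, defined as the MRCA of two tip sets
    (typically the two members of one trans-isthmian pair)."""

    name: str
    tips_a: frozenset[str]
    tips_b: frozenset[str]

    def __post_init__(self):
        if not self.tips_a or not self.tips_b:
            raise ValueError(f"pair {self.name!r}: both tip sets must be non-empty")

    @property
    def all_tips(self) -> frozenset[str]:
        return self.tips_a | self.tips_b


@dataclass(frozen=True)
class PairComparison:
    """One ordered comparison: fraction of trees where A's node is older."""

    pair_a: str
    pair_b: str
    n: int
    p_a_older: float
    ln_bf: float  # +/- inf at the p in {0, 1} boundary
    ln_bf_bound: float  # largest lnBF resolvable with n trees


@dataclass
class AsynchronyResult:
    ages: dict[str, np.ndarray]
    hpd: dict[str, tuple[float, float]]
    comparisons: list[PairComparison]
    n_trees: int
    plot_sample: dict[str, np.ndarray] = field(default_factory=dict)


def extract_tmrca_samples(sample: TreeSample, pair: GeminatePair) -> np.ndarray:
    """tMRCA of the pair's node in every tree, in sample order."""
    want = pair.all_tips
    ages = np.empty(len(sample))
    for i, tree in enumerate(sample):
        missing = want - tree.tip_labels
        if missing:
            raise TreeError(
                f"tree {i} lacks tip(s) {', '.join(sorted(missing))} "
                f"needed by pair {pair.name!r}"
            )
        ages[i] = tree.mrca(want).age
    return ages


def asynchrony_fraction(ages_a: Sequence[float], ages_b: Sequence[float]) -> float:
    """Paired fraction of trees in which node A is older than node B.

    Ties count one half, which makes the fraction antisymmetric under
    swapping the arguments (ties have measure zero for continuous ages).
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired age vectors differ in length: {a.size} vs {b.size}")
    n = a.size
    if n == 0:
        raise ValueError("empty age vectors")
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / n)


def ln_bayes_factor(p: float, prior_odds: float = 1.0) -> float:
    """ln Bayes factor for "node A is older": ln(p/(1-p)) - ln(prior odds)."""
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"p={p} is at the boundary: report '> largest resolvable lnBF for n trees' "
            "(ln((n - 0.5) / 0.5) at prior odds 1) instead of a finite value"
        )
    if prior_odds <= 0:
        raise ValueError(f"prior odds must be positive, got {prior_odds}")
    return math.log(p / (1.0 - p)) - math.log(prior_odds)


def geminate_report(
    sample: TreeSample,
    pairs: Sequence[GeminatePair],
    mass: float = 0.95,
    prior_odds: float = 1.0,
    n_plot: int = 100,
    seed: int = 0,
) -> AsynchronyResult:
    """Full asynchrony analysis over a posterior sample.

    For every unordered pair of geminate pairs, reports the paired
    older-than fraction (first-named pair older) and its lnBF; also
    returns per-pair HPD intervals and a seeded down-sample of the age
    vectors (default 100 trees) for plotting.
    """
    if len(pairs) < 2:
        raise ValueError("asynchrony needs at least 2 geminate pairs")
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError("geminate pair names must be unique")

    ages = {p.name: extract_tmrca_samples(sample, p) for p in pairs}
    n = len(sample)
    hpd = {name: hpd_interval(a, mass) for name, a in ages.items()}
    bound = math.log((n - 0.5) / 0.5)

    comparisons = []
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            a, b = pairs[i].name, pairs[j].name
            p = asynchrony_fraction(ages[a], ages[b])
            if p <= 0.0:
                lnbf = -math.inf
            elif p >= 1.0:
                lnbf = math.inf
            else:
                lnbf = ln_bayes_factor(p, prior_odds)
            comparisons.append(PairComparison(a, b, n, p, lnbf, bound))

    rng = np.random.default_rng(seed)
    k = min(n_plot, n)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    plot_sample = {name: a[idx] for name, a in ages.items()}
    return AsynchronyResult(ages, hpd, comparisons, n, plot_sample)


def read_pairs_config(path) -> list[GeminatePair]:
    """TSV: pair name, comma-joined tips A, comma-joined tips B."""
    pairs: list[GeminatePair] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated fields")
            name, a, b = parts
            pairs.append(
                GeminatePair(
                    name,
                    frozenset(x.strip() for x in a.split(",") if x.strip()),
                    frozenset(x.strip() for x in b.split(",") if x.strip()),
                )
            )
    return pairs
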