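"""Posterior tree-sample utilities.

A Bayesian dated-tree sampler emits an ordered sample of chronograms on
one tip set plus scalar traces (likelihood, rates...).  This module
provides the standard post-processing steps applied before any analysis
that consumes the sample: burn-in removal, clade frequencies, the
maximum clade credibility (MCC) tree, effective sample size of a trace,
and highest posterior density (HPD) intervals.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .tree import Chronogram, TreeError

__all__ = [
    "TreeSample",
    "discard_burnin",
    "clade_frequencies",
    "mcc_tree",
    "ess",
    "hpd_interval",
]


class TreeSample:
    """Ordered collection of chronograms on an identical tip set.

    Ordering is meaningful: burn-in removal drops a prefix, and paired
    node-age comparisons rely on tree *i* in one extraction matching
    tree *i* in another.

    Parameters
    ----------
    trees:
        Chronograms sharing one tip label set, in sampler order.
    traces:
        Optional named per-tree scalar traces (same length as trees).
    """

    def __init__(self, trees: Sequence[Chronogram], traces: dict[str, Sequence[float]] | None = None):
        trees = list(trees)
        if not trees:
            raise TreeError("a tree sample must contain at least one tree")
        ref = trees[0].tip_labels
        for i, t in enumerate(trees[1:], start=1):
            if t.tip_labels != ref:
                diff = sorted(ref ^ t.tip_labels)
                raise TreeError(
                    f"tree {i} tip set differs from tree 0: " + ", ".join(diff)
                )
        self.trees = trees
        self.traces = {k: list(v) for k, v in (traces or {}).items()}
        for name, tr in self.traces.items():
            if len(tr) != len(trees):
                raise TreeError(f"trace {name!r} length {len(tr)} != sample size {len(trees)}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> frozenset[str]:
        return self.trees[0].tip_labels


def discard_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Drop the first ``ceil(fraction * n)`` trees (and trace entries)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
    n = len(sample)
    drop = math.ceil(fraction * n)
    if drop >= n:
        raise TreeError("burn-in would discard the entire sample")
    return TreeSample(
        sample.trees[drop:],
        {k: v[drop:] for k, v in sample.traces.items()},
    )


def clade_frequencies(sample: TreeSample) -> dict[frozenset, float]:
    """Frequency of every observed clade (tip set) across the sample.

    Trivial clades — single tips and the full tip set — appear with
    frequency 1 in every sample.
    """
    counts: dict[frozenset, int] = {}
    for tree in sample:
        for clade in set(tree.clade_sets().values()):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(sample)
    return {clade: c / n for clade, c in counts.items()}


def mcc_tree(sample: TreeSample) -> tuple[Chronogram, dict[frozenset, float]]:
    """Maximum clade credibility member of the sample.

    The returned tree maximizes the sum of log clade frequencies over
    its internal clades (equivalently the product of clade supports);
    ties are broken by earliest sample index.  The second return value
    maps each internal clade of the winner to its frequency, i.e. the
    per-node posterior support annotation.  Node ages are the member
    tree's own ages (no re-annotation with mean or median heights).
    """
    freqs = clade_frequencies(sample)
    best_idx, best_score = 0, -math.inf
    scores = []
    for i, tree in enumerate(sample):
        clades = [c for n, c in tree.clade_sets().items()
                  if not tree.nodes[n].is_tip]
        score = sum(math.log(freqs[c]) for c in clades)
        scores.append(score)
        if score > best_score:
            best_idx, best_score = i, score
    winner = sample[best_idx]
    support = {
        c: freqs[c]
        for n, c in winner.clade_sets().items()
        if not winner.nodes[n].is_tip
    }
    return winner, support


def ess(trace: Sequence[float]) -> float:
    """Effective sample size of an autocorrelated scalar trace.

    Uses ``n / (1 + 2 * sum_k rho_k)`` with empirical autocorrelations
    summed up to (excluding) the first non-positive term — the simple
    initial-positive truncation rule.  No upper cap is applied, so an
    anticorrelated trace can report an ESS above ``n``.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"ESS needs at least 10 samples, got {n}")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        raise ValueError("zero-variance trace: autocorrelation undefined")
    # biased autocovariance estimates, as is standard for ESS
    acc = 0.0
    for k in range(1, n):
        rho = float(np.dot(x[:-k], x[k:])) / n / c0
        if rho <= 0.0:
            break
        acc += rho
    return n / (1.0 + 2.0 * acc)


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ``mass``.

    The interval contains ``ceil(mass * n)`` sample points; among
    equal-width candidates the lower one is returned.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("HPD needs at least 2 samples")
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    m = math.ceil(mass * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) minimum
    return float(x[i]), float(x[i + m - 1])
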