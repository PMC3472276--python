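"""Nonparametric rate smoothing (NPRS).

Transforms a phylogram (branch lengths in expected substitutions per
site) into a relative-time chronogram by choosing internal node ages
that minimise the sum of squared differences between the implied
substitution rates of adjacent branches,

    sum over internal non-root nodes v, children c of v of
        (rate(parent branch of v) - rate(branch v->c))^2,

with rate = branch length / time duration.  The root has no parent
branch, so only nodes carrying both a parent branch and child branches
contribute.  Tips sit at age 0 and the root age is fixed (default 1:
the output timescale is relative, not calibrated).

Ages are parameterised as logistic fractions of the parent's age,
guaranteeing the root > internal > tip ordering during unconstrained
optimisation; three starts (node-depth heuristic, equal splits, seeded
random) guard against local optima.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from .tree import Chronogram, RootedTree, TreeError

__all__ = ["nprs_chronogram"]


def nprs_chronogram(
    phylogram: RootedTree,
    root_age: float = 1.0,
    seed: int = 0,
    n_random_starts: int = 1,
) -> tuple[Chronogram, float]:
    """Smooth a phylogram into an ultrametric chronogram.

    Returns the chronogram (tips at 0, root at ``root_age``) and the
    achieved rate-smoothness objective (0 for an exactly clock-like
    input).  Scaling every input branch length by a constant leaves the
    chronogram unchanged.
    """
    phylogram.require_bifurcating()
    if phylogram.n_tips < 3:
        raise TreeError("NPRS needs at least 3 tips")
    if root_age <= 0:
        raise ValueError(f"root age must be positive, got {root_age}")
    for node in phylogram.nodes:
        if node is phylogram.root or node.is_tip:
            continue
        if node.length == 0:
            raise TreeError(
                "zero-length internal branch: collapse the polytomy or add "
                "a small jitter before smoothing"
            )

    tree = phylogram.copy()
    # free nodes: internal, non-root, in preorder so parents precede children
    free = [n for n in tree.preorder() if not n.is_tip and n is not tree.root]
    slot = {n.index: i for i, n in enumerate(free)}
    blen = {n.index: float(n.length) for n in tree.nodes if n is not tree.root}

    # mean branch length, for scale-invariant rate units
    scale = np.mean([b for b in blen.values() if b > 0]) or 1.0

    def ages_from(x: np.ndarray) -> dict[int, float]:
        ages = {tree.root.index: root_age}
        for n in free:
            frac = 1.0 / (1.0 + math.exp(-x[slot[n.index]]))
            ages[n.index] = frac * ages[n.parent.index]
        for n in tree.nodes:
            if n.is_tip:
                ages[n.index] = 0.0
        return ages

    def objective(x: np.ndarray) -> float:
        ages = ages_from(x)
        total = 0.0
        for v in free:  # only nodes with both parent and child branches
            dur_p = ages[v.parent.index] - ages[v.index]
            if dur_p <= 0:
                return 1e12
            r_p = blen[v.index] / dur_p / scale
            for c in v.children:
                dur_c = ages[v.index] - ages[c.index]
                if dur_c <= 0:
                    return 1e12
                r_c = blen[c.index] / dur_c / scale
                total += (r_p - r_c) ** 2
        return total

    depths = tree.depths()
    height = {}  # max path length from node down to a tip
    for n in tree.postorder():
        height[n.index] = 0.0 if n.is_tip else max(
            height[c.index] + float(c.length) for c in n.children
        )

    def logit(p):
        p = min(max(p, 1e-6), 1 - 1e-6)
        return math.log(p / (1.0 - p))

    starts = []
    # (i) node-depth heuristic: age proportional to height below the node
    starts.append(np.array([
        logit(height[n.index] / height[n.parent.index])
        if height[n.parent.index] > 0 else 0.0
        for n in free
    ]))
    # (ii) equal splits
    starts.append(np.zeros(len(free)))
    # (iii) seeded random
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(rng.normal(0.0, 1.0, size=len(free)))

    best_x, best_f = None, math.inf
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is None or not math.isfinite(best_f):
        raise RuntimeError("NPRS failed to converge from all starts")

    ages = ages_from(best_x)
    for n in tree.nodes:
        n.age = ages[n.index]
    chrono = Chronogram.from_ages(tree.root)
    # undo the internal rate rescaling: report the objective in
    # (branch length / time)^2 units
    return chrono, best_f * scale * scale
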