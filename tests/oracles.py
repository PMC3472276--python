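"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: Taylor-series matrix
exponentials, explicit enumeration over internal-state assignments and
cladogenetic histories, exhaustive minimum-cost searches.  None of it
shares code with the package's pruning/DP machinery beyond the tree
containers themselves.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def expm_series(Q: np.ndarray, t: float, terms: int = 30) -> np.ndarray:
    """exp(Qt) via scaling-and-squaring of a plain Taylor series."""
    Q = np.asarray(Q, dtype=float)
    A = Q * t
    norm = np.abs(A).sum(axis=1).max()
    k = max(0, int(math.ceil(math.log2(norm / 0.5)))) if norm > 0.5 else 0
    A = A / (2 ** k)
    n = Q.shape[0]
    P = np.eye(n)
    term = np.eye(n)
    for i in range(1, terms):
        term = term @ A / i
        P = P + term
    for _ in range(k):
        P = P @ P
    return P


# ----------------------------------------------------------------------
# binary-trait (Mk) enumeration


def mk_enumerate(chrono, trait, model):
    """Sum over all internal-state assignments of the joint probability.

    Returns (log-likelihood, {internal node index: (P0, P1)} marginals).
    """
    Q = np.array([[-model.q01, model.q01], [model.q10, -model.q10]])
    prior = model.prior_vector()
    internals = [n for n in chrono.nodes if not n.is_tip]
    edges = [
        (n.parent.index, n.index, n.parent.age - n.age)
        for n in chrono.nodes if n.parent is not None
    ]
    P = {(p, c): expm_series(Q, t) for p, c, t in edges}
    tip_state = {n.index: trait[n.label] for n in chrono.nodes if n.is_tip}

    total = 0.0
    marg = {n.index: np.zeros(2) for n in internals}
    for assign in itertools.product((0, 1), repeat=len(internals)):
        state = dict(tip_state)
        for node, s in zip(internals, assign):
            state[node.index] = s
        prob = prior[state[chrono.root.index]]
        for p, c, _ in edges:
            prob *= P[(p, c)][state[p], state[c]]
        total += prob
        for node, s in zip(internals, assign):
            marg[node.index][s] += prob
    marginals = {
        idx: tuple(v / total) for idx, v in marg.items()
    }
    return math.log(total), marginals


# ----------------------------------------------------------------------
# DEC enumeration (independent state space, scenarios and expm)


def _dec_states(areas, max_range):
    cap = len(areas) if max_range is None else min(max_range, len(areas))
    out = []
    for size in range(1, cap + 1):
        out.extend(frozenset(c) for c in itertools.combinations(areas, size))
    return out


def _dec_Q_dict(states, areas, d, e):
    """Rate dict {(from, to): rate} built directly from the event rules."""
    allstates = states + [frozenset()]
    Q = {}
    for r in states:
        for a in areas:
            if a not in r and (r | {a}) in allstates and (r | {a}) in states:
                Q[(r, r | {a})] = Q.get((r, r | {a}), 0.0) + d * len(r)
        for a in r:
            Q[(r, r - {a})] = Q.get((r, r - {a}), 0.0) + e
    k = len(allstates)
    idx = {s: i for i, s in enumerate(allstates)}
    M = np.zeros((k, k))
    for (x, y), rate in Q.items():
        M[idx[x], idx[y]] = rate
    np.fill_diagonal(M, -M.sum(axis=1))
    return M, idx, allstates


def _dec_splits(r):
    if len(r) == 1:
        return [(r, r)]
    out = set()
    for a in r:
        single = frozenset((a,))
        out |= {(single, r), (r, single), (single, r - single), (r - single, single)}
    return sorted(out, key=lambda p: (sorted(p[0]), sorted(p[1])))


def dec_enumerate(chrono, ranges, areas_codes, d, e, max_range=None):
    """Brute-force DEC likelihood and node marginals on a tiny tree.

    Sums over root states, every cladogenetic scenario at every node and
    every per-branch end state, with series-expansion transition
    probabilities.  Returns (log-likelihood, {node index: {range: P}}).
    """
    areas = list(areas_codes)
    states = _dec_states(areas, max_range)
    M, idx, allstates = _dec_Q_dict(states, areas, d, e)
    Pcache = {}

    def P(t):
        key = round(t, 15)
        if key not in Pcache:
            Pcache[key] = expm_series(M, t)
        return Pcache[key]

    def below(node, r, constraint=None):
        """P(data below node | pre-split range r), honouring an optional
        (node index, range) constraint."""
        if constraint is not None and constraint[0] == node.index:
            if r != constraint[1]:
                return 0.0
        if node.is_tip:
            return 1.0 if frozenset(ranges[node.label]) == r else 0.0
        splits = _dec_splits(r)
        total = 0.0
        for s1, s2 in splits:
            factor = 1.0
            for child, start in zip(node.children, (s1, s2)):
                t = node.age - child.age
                acc = 0.0
                for y in states:
                    p = P(t)[idx[start], idx[y]]
                    if p > 0:
                        acc += p * below(child, y, constraint)
                factor *= acc
            total += factor / len(splits)
        return total

    prior = 1.0 / len(states)
    lik = sum(prior * below(chrono.root, r) for r in states)
    marginals = {}
    for node in chrono.nodes:
        if node.is_tip:
            continue
        dist = {}
        for r in states:
            joint = sum(
                prior * below(chrono.root, r0, constraint=(node.index, r))
                for r0 in states
            )
            if joint > 0:
                dist[r] = joint / lik
        marginals[node.index] = dist
    return math.log(lik), marginals


# ----------------------------------------------------------------------
# DIVA exhaustive minimum


def diva_enumerate(tree, ranges, areas_codes, max_range=None):
    """Exhaustive min event cost over all internal range assignments and
    all split choices; returns (min cost, {node index: optimal ranges})."""
    areas = list(areas_codes)
    states = _dec_states(areas, max_range)
    internals = [n for n in tree.nodes if not n.is_tip]

    def allsplits(r):
        if len(r) == 1:
            return [(r, r)]
        items = sorted(r)
        out = []
        for bits in range(1, 2 ** len(items) - 1):
            s1 = frozenset(items[i] for i in range(len(items)) if bits >> i & 1)
            s2 = r - s1
            if s1 in set(states) and s2 in set(states):
                out.append((s1, s2))
        return out

    best = math.inf
    optimal = {n.index: set() for n in tree.nodes}
    for assign in itertools.product(states, repeat=len(internals)):
        state = {n.index: r for n, r in zip(internals, assign)}
        for n in tree.nodes:
            if n.is_tip:
                state[n.index] = frozenset(ranges[n.label])
        cost = 0.0
        for node in internals:
            r = state[node.index]
            node_best = math.inf
            for s1, s2 in allsplits(r):
                c = sum(
                    len(piece ^ state[child.index])
                    for piece, child in zip((s1, s2), node.children)
                )
                node_best = min(node_best, c)
            cost += node_best
        if cost < best - 1e-12:
            best = cost
            optimal = {i: {state[i]} for i in state}
        elif abs(cost - best) <= 1e-12:
            for i in state:
                optimal[i].add(state[i])
    return int(best), optimal
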