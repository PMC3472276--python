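"""Ancestral-range reconstruction: DEC likelihood and DIVA parsimony.

Geographic ranges are non-empty subsets of a small set of areas (the
motivating system uses WA = western Atlantic, EP = eastern Pacific,
IP = Indo-Pacific).  Two reconstructions are provided:

* **DEC** (dispersal-extinction-cladogenesis): ranges evolve along
  branches under a continuous-time Markov chain — dispersal adds an
  area at rate ``d`` (optionally modulated by an area-pair multiplier
  matrix), local extinction removes one at rate ``e`` — and split at
  nodes under the classic cladogenetic scenarios (single-area
  inheritance, subset sympatry, one-area-versus-rest vicariance), each
  allowed scenario receiving equal probability.  The empty range is an
  absorbing state contributing zero likelihood.  Maximum-likelihood
  ``d, e`` and marginal node ranges come from pruning with an
  outside/inside pass.

* **DIVA** (dispersal-vicariance analysis): Sankoff event-cost
  parsimony where vicariance and duplication are free while each
  dispersal (area gained) and extinction (area lost) along a branch
  costs 1; all minimum-cost range assignments per node are returned.

Following the sample-and-summarize design used with Bayesian tree
samplers, :func:`posterior_range_summary` applies either method to a
random draw of posterior trees and tabulates per-clade range
frequencies (the tabular equivalent of per-node pie charts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from .posterior import TreeSample
from .tree import Chronogram, RootedTree, TreeError

__all__ = [
    "AreaSet",
    "DECParams",
    "range_states",
    "build_dec_Q",
    "dec_loglik",
    "fit_dec",
    "dec_ancestral_ranges",
    "diva_parsimony",
    "posterior_range_summary",
    "read_range_table",
]

RATE_LO = 1e-9
RATE_HI = 1e3


@dataclass(frozen=True)
class AreaSet:
    """Ordered collection of unique area codes (at least two)."""

    codes: tuple[str, ...]

    def __post_init__(self):
        if len(self.codes) < 2:
            raise ValueError("an area set needs at least 2 areas")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError(f"duplicate area codes in {self.codes}")

    def __len__(self):
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)


@dataclass(frozen=True)
class DECParams:
    """Dispersal and local-extinction rates, per unit branch time.

    ``multipliers`` is an optional square matrix (source area x target
    area) scaling dispersal between specific area pairs; ``max_range``
    caps how many areas a single lineage may occupy (default: all).
    """

    d: float
    e: float
    max_range: int | None = None
    multipliers: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        for name, v in (("d", self.d), ("e", self.e)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.max_range is not None and self.max_range < 1:
            raise ValueError("max_range must be >= 1")


def range_states(areas: AreaSet, max_range: int | None = None) -> list[frozenset[str]]:
    """All non-empty ranges up to ``max_range`` areas, then the empty set.

    Ordered by range size then by area order, with the absorbing empty
    range last — this is the state order of :func:`build_dec_Q`.
    """
    cap = len(areas) if max_range is None else min(max_range, len(areas))
    states: list[frozenset[str]] = []
    codes = list(areas)
    for size in range(1, cap + 1):
        for combo in itertools.combinations(codes, size):
            states.append(frozenset(combo))
    states.append(frozenset())
    return states


def build_dec_Q(areas: AreaSet, params: DECParams) -> np.ndarray:
    """Anagenetic DEC rate matrix over the :func:`range_states` order."""
    states = range_states(areas, params.max_range)
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    mult = params.multipliers
    if mult is not None and (
        len(mult) != len(areas) or any(len(row) != len(areas) for row in mult)
    ):
        raise ValueError("multiplier matrix must be square over the area set")
    Q = np.zeros((k, k))
    for i, r in enumerate(states):
        if not r:
            continue  # empty range is absorbing
        for a in areas:
            if a in r:
                continue
            target = r | {a}
            if target not in index:
                continue  # exceeds max_range
            if mult is None:
                rate = params.d * len(r)
            else:
                ai = areas.index(a)
                rate = params.d * sum(mult[areas.index(b)][ai] for b in r)
            Q[i, index[target]] += rate
        for a in r:
            Q[i, index[r - {a}]] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def cladogenetic_scenarios(r: frozenset[str]) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Allowed (left, right) daughter ranges at a node whose range is ``r``.

    Single-area ranges are inherited identically by both daughters;
    multi-area ranges split by subset sympatry (one daughter keeps the
    full range, the other one of its areas) or vicariance (one daughter
    one area, the other the rest).  Ordered pairs are deduplicated.
    """
    if not r:
        return []
    if len(r) == 1:
        return [(r, r)]
    out: set[tuple[frozenset[str], frozenset[str]]] = set()
    for a in r:
        single = frozenset((a,))
        rest = r - single
        out.add((single, r))
        out.add((r, single))
        out.add((single, rest))
        out.add((rest, single))
    return sorted(out, key=lambda p: (sorted(p[0]), sorted(p[1])))


# ----------------------------------------------------------------------
# likelihood machinery


class _DecEngine:
    """Precomputed state space, scenario tables and branch propagators."""

    def __init__(self, chrono: Chronogram, ranges: Mapping[str, frozenset[str]],
                 areas: AreaSet, max_range: int | None):
        chrono.require_bifurcating()
        self.chrono = chrono
        self.areas = areas
        self.states = range_states(areas, max_range)
        self.k = len(self.states)
        self.index = {s: i for i, s in enumerate(self.states)}
        self.nonempty = np.arange(self.k - 1)
        # scenario tables: per ancestral state, daughter index arrays + weight
        self.scen: list[tuple[np.ndarray, np.ndarray, float]] = []
        for s in self.states:
            pairs = cladogenetic_scenarios(s)
            if not pairs:
                self.scen.append((np.empty(0, int), np.empty(0, int), 0.0))
            else:
                i1 = np.array([self.index[p[0]] for p in pairs])
                i2 = np.array([self.index[p[1]] for p in pairs])
                self.scen.append((i1, i2, 1.0 / len(pairs)))
        # tip partials
        self.tipL: dict[int, np.ndarray] = {}
        for tip in chrono.tips:
            if tip.label not in ranges:
                raise TreeError(f"no range observation for tip {tip.label!r}")
            obs = frozenset(ranges[tip.label])
            if not obs or obs not in self.index:
                raise TreeError(
                    f"tip {tip.label!r} range {sorted(obs)} is not a valid state"
                )
            v = np.zeros(self.k)
            v[self.index[obs]] = 1.0
            self.tipL[tip.index] = v
        self.internal = [
            (n.index, n.children[0].index, n.children[1].index,
             n.age - n.children[0].age, n.age - n.children[1].age)
            for n in chrono.postorder() if not n.is_tip
        ]
        self.root_index = chrono.root.index

    def propagators(self, params: DECParams) -> dict[float, np.ndarray]:
        Q = build_dec_Q(self.areas, replace_max(params, self.states))
        durations = sorted({t for item in self.internal for t in item[3:5]})
        out = {}
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            cond_ok = np.linalg.cond(V) < 1e8
        except np.linalg.LinAlgError:
            cond_ok = False
        for t in durations:
            if cond_ok:
                P = (V * np.exp(w * t)) @ Vinv
                P = np.real(P)
            else:  # defective or ill-conditioned eigenbasis
                P = linalg.expm(Q * t)
            np.clip(P, 0.0, None, out=P)
            out[t] = P
        return out

    def down_pass(self, params: DECParams, constraint: tuple[int, int] | None = None):
        """Pruning; returns (per-node partials, log scale, loglik).

        ``constraint=(node_index, state_index)`` zeroes every other
        state at that node's pre-cladogenesis partial (used for
        constrained marginals in testing).
        """
        P = self.propagators(params)
        L: dict[int, np.ndarray] = dict(self.tipL)
        logscale = 0.0
        for node, l, r, tl, tr in self.internal:
            Dl = P[tl] @ L[l]
            Dr = P[tr] @ L[r]
            anc = np.zeros(self.k)
            for i in range(self.k - 1):  # skip empty state
                i1, i2, w = self.scen[i]
                anc[i] = w * float(np.dot(Dl[i1], Dr[i2]))
            if constraint is not None and constraint[0] == node:
                mask = np.zeros(self.k)
                mask[constraint[1]] = 1.0
                anc = anc * mask
            m = anc.max()
            if m > 0:
                anc /= m
                logscale += math.log(m)
            L[node] = anc
        if constraint is not None and self.tipL.get(constraint[0]) is not None:
            raise ValueError("constraints apply to internal nodes only")
        prior = 1.0 / (self.k - 1)
        lik = float(L[self.root_index][: self.k - 1].sum() * prior)
        loglik = math.log(lik) + logscale if lik > 0 else -math.inf
        return L, P, logscale, loglik


def replace_max(params: DECParams, states: Sequence[frozenset]) -> DECParams:
    """Pin max_range to the engine's state space (idempotent helper)."""
    cap = max(len(s) for s in states)
    if params.max_range == cap:
        return params
    return DECParams(params.d, params.e, cap, params.multipliers)


def dec_loglik(
    chrono: Chronogram,
    ranges: Mapping[str, frozenset[str]],
    params: DECParams,
    areas: AreaSet,
) -> float:
    """DEC log-likelihood of tip ranges on a bifurcating chronogram.

    Root states receive a flat prior over non-empty ranges.
    """
    eng = _DecEngine(chrono, ranges, areas, params.max_range)
    return eng.down_pass(params)[3]


def fit_dec(
    chrono: Chronogram,
    ranges: Mapping[str, frozenset[str]],
    areas: AreaSet,
    max_range: int | None = None,
    multipliers=None,
    n_starts: int = 3,
) -> tuple[DECParams, float]:
    """Maximum-likelihood dispersal and extinction rates.

    2-D Nelder-Mead on log rates with multiple starts; rates bounded to
    [1e-9, 1e3] inside the objective.
    """
    eng = _DecEngine(chrono, ranges, areas, max_range)
    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def nll(x):
        d = float(np.exp(np.clip(x[0], lo, hi)))
        e = float(np.exp(np.clip(x[1], lo, hi)))
        return -eng.down_pass(DECParams(d, e, max_range, multipliers))[3]

    starts = [
        (math.log(0.1), math.log(0.1)),
        (math.log(0.5), math.log(0.05)),
        (math.log(0.02), math.log(0.02)),
        (math.log(1.0), math.log(0.5)),
    ][: max(n_starts, 1)]
    best_x, best_f = None, math.inf
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is None or not math.isfinite(best_f):
        grid = [(d, e) for d in (0.01, 0.1, 1.0) for e in (0.01, 0.1, 1.0)]
        diag = {de: -eng.down_pass(DECParams(*de, max_range, multipliers))[3] for de in grid}
        raise RuntimeError(f"DEC fit failed to converge; grid diagnostics: {diag}")
    d = float(np.exp(np.clip(best_x[0], lo, hi)))
    e = float(np.exp(np.clip(best_x[1], lo, hi)))
    return DECParams(d, e, max_range, multipliers), -best_f


def dec_ancestral_ranges(
    chrono: Chronogram,
    ranges: Mapping[str, frozenset[str]],
    params: DECParams,
    areas: AreaSet,
) -> dict[int, dict[frozenset[str], float]]:
    """Marginal posterior over each internal node's range (pre-split).

    Outside/inside pass analogous to the binary-trait machinery but with
    the cladogenetic scenario sum folded into the outside messages.
    Keys are node indices; each inner distribution sums to 1.
    """
    eng = _DecEngine(chrono, ranges, areas, params.max_range)
    L, P, _, loglik = eng.down_pass(params)
    if not math.isfinite(loglik):
        raise TreeError("data have zero likelihood under the supplied DEC parameters")
    k = eng.k
    prior = np.zeros(k)
    prior[: k - 1] = 1.0 / (k - 1)

    # D[child] = P(t) @ L[child] messages, cached per internal node
    D: dict[int, np.ndarray] = {}
    for node, l, r, tl, tr in eng.internal:
        D[l] = P[tl] @ L[l]
        D[r] = P[tr] @ L[r]

    U: dict[int, np.ndarray] = {eng.root_index: prior}
    for node, l, r, tl, tr in reversed(eng.internal):
        u = U[node]
        for child, sib, tc in ((l, r, tl), (r, l, tr)):
            msg = np.zeros(k)  # message to the child's branch top
            for i in range(k - 1):
                if u[i] == 0:
                    continue
                i1, i2, w = eng.scen[i]
                if child == l:
                    contrib = w * u[i] * np.bincount(
                        i1, weights=D[sib][i2], minlength=k
                    )
                else:
                    contrib = w * u[i] * np.bincount(
                        i2, weights=D[sib][i1], minlength=k
                    )
                msg += contrib
            g = msg @ P[tc]  # propagate down the child's branch
            m = g.max()
            U[child] = g / m if m > 0 else g

    out: dict[int, dict[frozenset[str], float]] = {}
    for node in chrono.nodes:
        if node.is_tip:
            continue
        w = U[node.index] * L[node.index]
        total = w.sum()
        if total <= 0:
            raise RuntimeError("zero marginal at an internal node")
        out[node.index] = {
            eng.states[i]: float(w[i] / total) for i in range(k - 1) if w[i] > 0
        }
    return out


# ----------------------------------------------------------------------
# DIVA event-cost parsimony


def diva_parsimony(
    tree: RootedTree,
    ranges: Mapping[str, frozenset[str]],
    max_range: int | None = None,
    areas: AreaSet | None = None,
) -> tuple[int, dict[int, set[frozenset[str]]]]:
    """Minimum-event-cost range reconstruction (dispersal-vicariance).

    Costs: each dispersal (area gained along a branch) and each local
    extinction (area lost) cost 1; vicariance (any bipartition of a
    multi-area range) and duplication (single-area inheritance) are
    free.  Returns the minimal total cost and, per node index, every
    range appearing in at least one globally optimal assignment.
    """
    tree.require_bifurcating()
    if areas is None:
        observed = sorted({a for r in ranges.values() for a in r})
        areas = AreaSet(tuple(observed))
    states = range_states(areas, max_range)[:-1]  # non-empty only
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    INF = float("inf")

    bcost = np.empty((k, k))
    for i, x in enumerate(states):
        for j, y in enumerate(states):
            bcost[i, j] = len(x ^ y)

    def splits(r: frozenset[str]):
        if len(r) == 1:
            yield (index[r], index[r])
            return
        items = sorted(r)
        for bits in range(1, 2 ** len(items) - 1):
            s1 = frozenset(items[i] for i in range(len(items)) if bits >> i & 1)
            s2 = r - s1
            if s1 in index and s2 in index:
                yield (index[s1], index[s2])

    split_table = {index[s]: list(splits(s)) for s in states}

    down = {}
    cmin = {}  # cmin[node][s] = min over y of bcost(s, y) + down[node][y]
    for node in tree.postorder():
        if node.is_tip:
            obs = frozenset(ranges[node.label])
            if obs not in index:
                raise TreeError(
                    f"tip {node.label!r} range {sorted(obs)} exceeds max_range"
                )
            vec = np.full(k, INF)
            vec[index[obs]] = 0.0
        else:
            l, r = node.children
            vec = np.full(k, INF)
            for i in range(k):
                best = INF
                for s1, s2 in split_table[i]:
                    c = cmin[l.index][s1] + cmin[r.index][s2]
                    if c < best:
                        best = c
                vec[i] = best
        down[node.index] = vec
        cmin[node.index] = np.min(bcost + vec[None, :], axis=1)

    total = float(np.min(down[tree.root.index]))

    up = {tree.root.index: np.zeros(k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        l, r = node.children
        u = up[node.index]
        for child, sib in ((l, r), (r, l)):
            msg = np.full(k, INF)  # min cost at top of child's branch
            for i in range(k):
                if not math.isfinite(u[i]):
                    continue
                for s1, s2 in split_table[i]:
                    sc, ss = (s1, s2) if child is l else (s2, s1)
                    c = u[i] + cmin[sib.index][ss]
                    if c < msg[sc]:
                        msg[sc] = c
            # propagate down the branch: up[child][y] = min_s msg[s] + bcost(s, y)
            up[child.index] = np.min(msg[:, None] + bcost, axis=0)

    optimal: dict[int, set[frozenset[str]]] = {}
    for node in tree.nodes:
        tot = down[node.index] + up[node.index]
        optimal[node.index] = {
            states[i] for i in range(k) if tot[i] <= total + 1e-9
        }
    return int(round(total)), optimal


# ----------------------------------------------------------------------
# posterior summarization


def posterior_range_summary(
    sample: TreeSample,
    ranges: Mapping[str, frozenset[str]],
    method: Literal["DEC", "DIVA"] = "DEC",
    n_trees: int = 500,
    seed: int = 0,
    areas: AreaSet | None = None,
    max_range: int | None = None,
    dec_params: DECParams | None = None,
    min_clade_fraction: float = 0.05,
) -> dict[frozenset[str], dict]:
    """Clade-wise ancestral-range frequencies over random posterior trees.

    Draws ``n_trees`` trees without replacement (seeded), reconstructs
    ancestral ranges on each (DEC: most probable marginal range, with
    ``d, e`` fitted per tree unless ``dec_params`` is given; DIVA:
    minimum-cost ranges, co-optimal ones sharing unit weight), and
    reports, for every internal clade present in at least
    ``min_clade_fraction`` of the evaluated trees, the frequency
    distribution of its reconstructed ranges plus its presence fraction.
    """
    if n_trees > len(sample):
        raise ValueError(f"n_trees={n_trees} exceeds sample size {len(sample)}")
    if areas is None:
        observed = sorted({a for r in ranges.values() for a in r})
        areas = AreaSet(tuple(observed))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sample), size=n_trees, replace=False)
    idx.sort()

    presence: dict[frozenset[str], int] = {}
    weight: dict[frozenset[str], dict[frozenset[str], float]] = {}
    for i in idx:
        tree = sample[int(i)]
        clades = tree.clade_sets()
        if method == "DEC":
            if dec_params is None:
                params, _ = fit_dec(tree, ranges, areas, max_range)
            else:
                params = dec_params
            marg = dec_ancestral_ranges(tree, ranges, params, areas)
            per_node = {
                n: {max(dist, key=dist.get): 1.0} for n, dist in marg.items()
            }
        elif method == "DIVA":
            _, opt = diva_parsimony(tree, ranges, max_range, areas)
            per_node = {
                n: {r: 1.0 / len(rs) for r in rs}
                for n, rs in opt.items()
                if not tree.nodes[n].is_tip
            }
        else:
            raise ValueError(f"unknown method {method!r}")
        for n, dist in per_node.items():
            clade = clades[n]
            presence[clade] = presence.get(clade, 0) + 1
            acc = weight.setdefault(clade, {})
            for r, w in dist.items():
                acc[r] = acc.get(r, 0.0) + w

    out: dict[frozenset[str], dict] = {}
    for clade, count in presence.items():
        frac = count / n_trees
        if frac < min_clade_fraction:
            continue
        dist = {r: w / count for r, w in weight[clade].items()}
        out[clade] = {"presence": frac, "ranges": dist}
    return out


def read_range_table(path, areas: AreaSet | None = None) -> dict[str, frozenset[str]]:
    """2-column TSV: tip label, comma-joined area codes."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            label, codes = parts
            r = frozenset(c.strip() for c in codes.split(",") if c.strip())
            if not r:
                raise ValueError(f"{path}:{line_no}: empty range for {label!r}")
            if areas is not None:
                bad = r - set(areas)
                if bad:
                    raise ValueError(
                        f"{path}:{line_no}: unknown area code(s) {sorted(bad)}"
                    )
            out[label] = r
    return out
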