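"""Seeded generators for every input the analyses consume.

The generators mirror the statistical structure of the real study
inputs: ultrametric trees from a pure-birth (Yule) prior, binary traits
under the 2-state Markov model, geographic ranges under
dispersal-extinction-cladogenesis with cladogenetic inheritance,
nucleotide alignments under GTR-family models with I+gamma site rates,
and posterior tree samples emulated by correlated lognormal node-age
jitter around a base chronogram.

Reproducibility policy: every generator takes an integer seed and is a
pure function of its arguments.  A :class:`SimulationConfig` bundle
derives independent named substreams from one root seed, so adding a
generator never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .biogeo import AreaSet, DECParams, build_dec_Q, cladogenetic_scenarios, range_states
from .distances import AlignedSequences, SubstModel
from .mk import MkModel, transition_matrix
from .posterior import TreeSample
from .tree import Chronogram, Node

__all__ = [
    "SimulationConfig",
    "substream",
    "simulate_yule",
    "simulate_mk_trait",
    "simulate_dec_ranges",
    "simulate_sequences",
    "emulate_posterior",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream derived from one root seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Bundle of generator settings with one root seed.

    Defaults reflect a mid-sized Bayesian dating study: a few dozen
    tips, a posterior of a few hundred trees, kilobase alignments and
    moderate trait/range rates on a relative timescale.
    """

    seed: int
    n_tips: int = 50
    birth_rate: float = 1.0
    mk_model: MkModel = field(default_factory=lambda: MkModel(1.0, 1.0, "ER"))
    dec_params: DECParams = field(default_factory=lambda: DECParams(0.2, 0.05))
    areas: AreaSet = field(default_factory=lambda: AreaSet(("WA", "EP", "IP")))
    subst_model: SubstModel = field(default_factory=SubstModel.jc69)
    seq_length: int = 1000
    n_posterior: int = 500
    age_jitter_sd: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory: every output must be reproducible")

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)


# ----------------------------------------------------------------------


def simulate_yule(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                  prefix: str = "t") -> Chronogram:
    """Pure-birth chronogram conditioned on ``n_tips`` extant tips.

    Growth starts from two lineages at the root; with k lineages the
    wait to the next split is Exponential(k * birth_rate).  After the
    n-th tip appears the process runs one further Exponential(n *
    birth_rate) stretch to the present, so the youngest internal node
    sits strictly above the tips.  Tips are labelled ``t1..tn``.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError(f"birth rate must be positive, got {birth_rate}")
    rng = np.random.default_rng(seed)

    root = Node()
    active = [root.add_child(Node()), root.add_child(Node())]
    split_time = {id(root): 0.0}
    now = 0.0
    while len(active) < n_tips:
        k = len(active)
        now += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        split_time[id(node)] = now
        active.extend((node.add_child(Node()), node.add_child(Node())))
    now += rng.exponential(1.0 / (n_tips * birth_rate))

    order = rng.permutation(n_tips)
    for j, tip in enumerate(active):
        tip.label = f"{prefix}{order[j] + 1}"
        tip.age = 0.0
    # ages: elapsed time is measured root->present; age = now - split time
    def set_ages(node: Node):
        if not node.is_tip:
            node.age = now - split_time[id(node)]
            for c in node.children:
                set_ages(c)
    set_ages(root)
    return Chronogram.from_ages(root)


def simulate_mk_trait(
    chrono: Chronogram,
    model: MkModel,
    root_state: int | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Evolve a binary state root-to-tips with the closed-form kernel."""
    rng = np.random.default_rng(seed)
    if root_state is None:
        prior = model.prior_vector()
        root_state = int(rng.random() < prior[1])
    state = {chrono.root.index: int(root_state)}
    for node in chrono.preorder():
        if node is chrono.root:
            continue
        t = node.parent.age - node.age
        P = transition_matrix(model, t)
        s = state[node.parent.index]
        state[node.index] = int(rng.random() < P[s, 1])
    return {n.label: state[n.index] for n in chrono.tips}


def simulate_dec_ranges(
    chrono: Chronogram,
    params: DECParams,
    areas: AreaSet,
    root_range: frozenset[str] | Sequence[str],
    seed: int = 0,
    max_rejections: int = 1000,
) -> dict[str, frozenset[str]]:
    """Evolve geographic ranges under DEC with cladogenetic inheritance.

    Anagenetic events along branches are drawn by Gillespie simulation
    from the DEC rate matrix; at every internal node the inheritance
    scenario is sampled uniformly from the allowed set.  A lineage that
    goes globally extinct (empty range) has its branch history redrawn
    — i.e. each branch is conditioned on survival; after
    ``max_rejections`` redraws of one branch an error suggests lowering
    the extinction rate.
    """
    root_range = frozenset(root_range)
    if not root_range:
        raise ValueError("root range must be non-empty")
    rng = np.random.default_rng(seed)
    states = range_states(areas, params.max_range)
    index = {s: i for i, s in enumerate(states)}
    if root_range not in index:
        raise ValueError(f"root range {sorted(root_range)} exceeds max_range")
    Q = build_dec_Q(areas, DECParams(params.d, params.e,
                                     params.max_range or len(areas),
                                     params.multipliers))
    empty = index[frozenset()]

    def evolve_once(start: int, t: float) -> int:
        s, remaining = start, t
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                return s
            wait = rng.exponential(1.0 / out_rate)
            if wait >= remaining:
                return s
            remaining -= wait
            probs = np.clip(Q[s].copy(), 0.0, None)
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(len(states), p=probs))

    def evolve_branch(start: int, t: float) -> int:
        for _ in range(max_rejections):
            end = evolve_once(start, t)
            if end != empty:
                return end
        raise RuntimeError(
            f"a lineage went globally extinct in {max_rejections} "
            "consecutive redraws: lower the extinction rate e"
        )

    state = {chrono.root.index: index[root_range]}
    for node in chrono.preorder():
        if node.is_tip:
            continue
        r = states[state[node.index]]
        scen = cladogenetic_scenarios(r)
        s1, s2 = scen[int(rng.integers(len(scen)))]
        for child, inherited in zip(node.children, (s1, s2)):
            state[child.index] = evolve_branch(index[inherited],
                                               node.age - child.age)
    return {n.label: states[state[n.index]] for n in chrono.tips}


def simulate_sequences(
    chrono_or_t: Chronogram | float,
    model: SubstModel,
    length: int,
    seed: int = 0,
) -> AlignedSequences:
    """Evolve nucleotide sequences under a GTR-family model with I+gamma.

    Given a chronogram, the root sequence is drawn from the stationary
    frequencies and evolved along every branch; per-site rates are
    drawn once from the I+gamma mixture and shared across the tree.
    Given a scalar ``t``, returns a two-sequence alignment ('a', 'b')
    separated by total divergence t.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs)
    rates, weights = model.rate_categories()
    site_rate = rates[rng.choice(rates.size, size=length, p=weights)]
    lam, left, right = model._eig()

    def evolve(parent_seq: np.ndarray, t: float) -> np.ndarray:
        child = parent_seq.copy()
        for r in np.unique(site_rate):
            cols = np.nonzero(site_rate == r)[0]
            if r == 0.0 or t == 0.0:
                continue
            P = np.clip(left @ (np.exp(lam * t * r)[:, None] * right), 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            for base in range(4):
                sel = cols[parent_seq[cols] == base]
                if sel.size:
                    child[sel] = rng.choice(4, size=sel.size, p=P[base])
        return child

    root_seq = rng.choice(4, size=length, p=pi)
    letters = np.array(list("ACGT"))
    if isinstance(chrono_or_t, (int, float)):
        other = evolve(root_seq, float(chrono_or_t))
        seqs = {"a": "".join(letters[root_seq]), "b": "".join(letters[other])}
        return AlignedSequences(seqs)

    chrono = chrono_or_t
    seq_at = {chrono.root.index: root_seq}
    for node in chrono.preorder():
        if node is chrono.root:
            continue
        t = node.parent.age - node.age
        seq_at[node.index] = evolve(seq_at[node.parent.index], t)
    seqs = {n.label: "".join(letters[seq_at[n.index]]) for n in chrono.tips}
    return AlignedSequences(seqs)


def emulate_posterior(
    base: Chronogram,
    n_trees: int,
    age_jitter_sd: float = 0.1,
    topology_swap_rate: float = 0.0,
    seed: int = 0,
    max_resample: int = 100,
) -> TreeSample:
    """Posterior-sample stand-in: jittered copies of one chronogram.

    Node ages are multiplied by correlated lognormal noise — one
    tree-level factor shared by all nodes plus an independent per-node
    factor, each with variance ``age_jitter_sd**2 / 2`` on the log
    scale, so ages within a tree co-vary the way posterior samples do.
    Draws violating the parent-older-than-child ordering are resampled
    (up to ``max_resample`` per tree).  ``topology_swap_rate`` applies
    a Poisson number of random age-respecting NNI swaps per tree.
    """
    if age_jitter_sd < 0:
        raise ValueError("jitter sd must be >= 0")
    rng = np.random.default_rng(seed)
    sd = age_jitter_sd / math.sqrt(2.0)
    trees = []
    for _ in range(n_trees):
        for attempt in range(max_resample):
            t = base.copy()
            f_tree = math.exp(rng.normal(0.0, sd)) if age_jitter_sd > 0 else 1.0
            ok = True
            for node in t.preorder():
                if node.is_tip:
                    node.age = 0.0
                    continue
                f_node = math.exp(rng.normal(0.0, sd)) if age_jitter_sd > 0 else 1.0
                node.age = node.age * f_tree * f_node
                if node.parent is not None and node.age >= node.parent.age:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                "could not draw an order-preserving jitter; lower age_jitter_sd"
            )
        if topology_swap_rate > 0:
            for _ in range(rng.poisson(topology_swap_rate)):
                _random_nni(t, rng)
        trees.append(Chronogram.from_ages(t.root))
    return TreeSample(trees)


def _random_nni(t: Chronogram, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange that keeps ages valid."""
    internal_edges = [
        n for n in t.nodes
        if not n.is_tip and n.parent is not None
    ]
    rng.shuffle(internal_edges)
    for v in internal_edges:
        u = v.parent
        sib = next(c for c in u.children if c is not v)
        child = v.children[int(rng.integers(2))]
        # swapping `sib` (new child of v) with `child` (new child of u)
        # is valid iff v is older than sib's age
        if v.age > sib.age:
            u.children[u.children.index(sib)] = child
            v.children[v.children.index(child)] = sib
            sib.parent, child.parent = v, u
            t._index()
            return
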