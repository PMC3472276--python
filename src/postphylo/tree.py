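"""Rooted trees, chronograms and Newick/NEXUS input/output.

The package's tree container is a plain rooted tree with branch lengths
(a *phylogram*, lengths in expected substitutions per site or any other
additive unit) or, for time-based analyses, a :class:`Chronogram` whose
nodes additionally carry ages (tips at age 0, ages increasing towards
the root, ultrametric within a relative tolerance).

Parsing of Newick strings and NEXUS ``trees`` blocks (including
``translate`` blocks as written by Bayesian tree samplers) is delegated
to :mod:`dendropy`; this module converts the result into the package's
own lightweight node structure and enforces the invariants downstream
analyses rely on: unique non-empty tip labels, finite non-negative
branch lengths present on every non-root edge, a single root.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "RootedTree",
    "Chronogram",
    "parse_newick",
    "write_newick",
    "parse_nexus_trees",
    "write_nexus_trees",
    "mrca",
    "tmrca",
    "is_ultrametric",
]

#: default relative tolerance for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed tree input or violated tree invariants."""


class Node:
    """A single node: tips carry a label, every non-root an edge length."""

    __slots__ = ("index", "label", "length", "parent", "children", "age")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.index: int = -1
        self.label = label
        self.length = length  # branch length to parent; None only at the root
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.age: float = 0.0

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.index} {kind} label={self.label!r} length={self.length}>"


class RootedTree:
    """Rooted tree with branch lengths.

    Nodes are indexed in postorder (tips and internals interleaved as
    encountered); ``nodes[i].index == i``.  The structure is mutable but
    analyses treat it as frozen; use :meth:`copy` before editing.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._index()
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    def _index(self) -> None:
        self.nodes: list[Node] = list(_postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.index = i

    def validate(self) -> None:
        labels = [n.label for n in self.tips]
        if any(not lab for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise TreeError(f"duplicate tip label {lab!r}")
            seen.add(lab)
        for node in self.nodes:
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"missing branch length on edge above {node.label or 'an internal node'}"
                )
            if not math.isfinite(node.length) or node.length < 0:
                raise TreeError(
                    f"invalid branch length {node.length!r} above {node.label or 'an internal node'}"
                )

    # ------------------------------------------------------------------
    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.tips)  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    def postorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def preorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def require_bifurcating(self) -> None:
        for n in self.nodes:
            if len(n.children) not in (0, 2):
                raise TreeError(
                    f"tree is not fully bifurcating: node {n.index} has "
                    f"{len(n.children)} children"
                )

    def clade_sets(self) -> dict[int, frozenset[str]]:
        """Tip-label set below each node, keyed by node index (postorder)."""
        out: dict[int, frozenset[str]] = {}
        for node in self.nodes:
            if node.is_tip:
                out[node.index] = frozenset((node.label,))  # type: ignore[arg-type]
            else:
                acc: frozenset[str] = frozenset()
                for ch in node.children:
                    acc |= out[ch.index]
                out[node.index] = acc
        return out

    def mrca(self, tips: Iterable[str]) -> Node:
        """Most recent common ancestor of a non-empty set of tip labels."""
        want = frozenset(tips)
        if not want:
            raise TreeError("mrca of an empty tip set is undefined")
        unknown = want - self.tip_labels
        if unknown:
            raise TreeError(f"unknown tip label(s): {', '.join(sorted(unknown))}")
        clades = self.clade_sets()
        best: Node | None = None
        for node in self.nodes:  # postorder: first superset is the smallest
            if want <= clades[node.index]:
                best = node
                break
        assert best is not None
        return best

    def depths(self) -> dict[int, float]:
        """Sum of branch lengths from the root to each node."""
        out: dict[int, float] = {self.root.index: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.index] = out[node.parent.index] + float(node.length)
        return out

    def copy(self) -> "RootedTree":
        return type(self)(_copy_subtree(self.root), validate=False)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.n_tips} tips>"


class Chronogram(RootedTree):
    """Ultrametric rooted tree; every node carries an age (tips at 0)."""

    @property
    def root_age(self) -> float:
        return self.root.age

    @classmethod
    def from_ages(cls, root: Node) -> "Chronogram":
        """Build from a node structure whose ``age`` fields are already set.

        Branch lengths are (re)derived as parent age minus child age.
        """
        chrono = cls(root, validate=False)
        for node in chrono.nodes:
            if node is not chrono.root:
                node.length = node.parent.age - node.age
        chrono.validate()
        chrono._validate_ages()
        return chrono

    @classmethod
    def from_phylogram(
        cls, tree: RootedTree, rel_tol: float = ULTRAMETRIC_RTOL
    ) -> "Chronogram":
        """Reinterpret an ultrametric phylogram's depths as ages."""
        ok, disc = is_ultrametric(tree, rel_tol)
        if not ok:
            raise TreeError(
                f"tree is not ultrametric: max root-to-tip discrepancy {disc:g} "
                f"exceeds relative tolerance {rel_tol:g}"
            )
        root = _copy_subtree(tree.root)
        chrono = cls(root, validate=False)
        depths = chrono.depths()
        root_age = max(depths[t.index] for t in chrono.tips)
        for node in chrono.nodes:
            node.age = 0.0 if node.is_tip else root_age - depths[node.index]
        for node in chrono.nodes:
            if node is not chrono.root:
                node.length = node.parent.age - node.age
        chrono.validate()
        chrono._validate_ages()
        return chrono

    def _validate_ages(self) -> None:
        scale = max(self.root.age, 1.0)
        for node in self.nodes:
            if not math.isfinite(node.age) or node.age < -1e-12 * scale:
                raise TreeError(f"invalid node age {node.age!r}")
            if node is not self.root and node.parent.age < node.age - 1e-9 * scale:
                raise TreeError(
                    f"parent age {node.parent.age:g} below child age {node.age:g}"
                )

    def tmrca(self, tip_a: str, tip_b: str) -> float:
        return self.mrca({tip_a, tip_b}).age

    def copy(self) -> "Chronogram":
        root = _copy_subtree(self.root)
        chrono = type(self)(root, validate=False)
        return chrono


# ----------------------------------------------------------------------
# free functions mirroring the class API


def mrca(tree: RootedTree, tips: Iterable[str]) -> Node:
    return tree.mrca(tips)


def tmrca(chrono: Chronogram, tip_a: str, tip_b: str) -> float:
    """Age of the most recent common ancestor of two tips (symmetric)."""
    if not isinstance(chrono, Chronogram):
        ok, disc = is_ultrametric(chrono, ULTRAMETRIC_RTOL)
        if not ok:
            raise TreeError(
                f"tmrca needs an ultrametric tree; max path discrepancy {disc:g}"
            )
        chrono = Chronogram.from_phylogram(chrono)
    return chrono.tmrca(tip_a, tip_b)


def is_ultrametric(
    tree: RootedTree, rel_tol: float = ULTRAMETRIC_RTOL
) -> tuple[bool, float]:
    """Whether all root-to-tip path lengths agree.

    Returns ``(flag, discrepancy)`` where discrepancy is the spread
    (max minus min) of root-to-tip sums; the flag is true when the
    spread is within ``rel_tol`` of the mean path length.
    """
    depths = tree.depths()
    tip_depths = [depths[t.index] for t in tree.tips]
    if len(tip_depths) < 2:
        raise TreeError("ultrametricity needs at least 2 tips")
    disc = max(tip_depths) - min(tip_depths)
    mean = sum(tip_depths) / len(tip_depths)
    return disc <= rel_tol * max(mean, 1e-300), disc


# ----------------------------------------------------------------------
# parsing / writing


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick string into a :class:`RootedTree`.

    Branch lengths are required on every non-root edge (downstream
    likelihood and age arithmetic needs them); polytomies are accepted
    here and rejected by the operations that cannot handle them.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise TreeError(f"malformed Newick: {exc}") from None
    return RootedTree(_from_dendropy(dtree.seed_node))


def write_newick(tree: RootedTree, digits: int = 10) -> str:
    """Plain Newick with branch lengths at ``digits`` significant digits."""
    fmt = f"%.{digits}g"

    def rec(node: Node) -> str:
        if node.is_tip:
            core = _quote_label(node.label)
        else:
            core = "(" + ",".join(rec(ch) for ch in node.children) + ")"
            if node.label:
                core += _quote_label(node.label)
        if node.parent is not None and node.length is not None:
            core += ":" + (fmt % node.length)
        return core

    return rec(tree.root) + ";"


def parse_nexus_trees(text: str):
    """Parse a NEXUS ``trees`` block into a posterior :class:`TreeSample`.

    Accepts translate blocks mapping integer tokens to labels as well as
    inline labels; square-bracket comments are stripped.  All trees must
    share one tip set and must be ultrametric (they are chronograms from
    a dated-tree sampler); ordering is preserved.
    """
    from .posterior import TreeSample  # local import to avoid a cycle

    try:
        dtrees = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed NEXUS: {exc}") from None
    if len(dtrees) == 0:
        raise TreeError("NEXUS input contains no trees")
    trees = [RootedTree(_from_dendropy(t.seed_node)) for t in dtrees]
    ref = trees[0].tip_labels
    for i, t in enumerate(trees[1:], start=1):
        if t.tip_labels != ref:
            diff = sorted(ref ^ t.tip_labels)
            raise TreeError(
                f"tree {i} tip set differs from tree 0; symmetric difference: "
                + ", ".join(diff)
            )
    return TreeSample([Chronogram.from_phylogram(t) for t in trees])


def write_nexus_trees(sample, translate: bool = True) -> str:
    """NEXUS trees block with a translate table (round-trips parse_nexus_trees)."""
    labels = sorted(sample.trees[0].tip_labels)
    number = {lab: i + 1 for i, lab in enumerate(labels)}
    lines = ["#NEXUS", "BEGIN TREES;"]
    if translate:
        body = ",\n".join(f"        {number[lab]} {_quote_label(lab)}" for lab in labels)
        lines.append("    TRANSLATE\n" + body + ";")

    for k, tree in enumerate(sample.trees):
        t = tree.copy()
        if translate:
            for tip in t.tips:
                tip.label = str(number[tip.label])
        lines.append(f"    TREE tree_{k} = {write_newick(t, digits=17)}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# helpers


def _postorder(root: Node) -> Iterator[Node]:
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for ch in reversed(node.children):
                stack.append((ch, False))


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length)
    new.age = node.age
    for ch in node.children:
        new.add_child(_copy_subtree(ch))
    return new


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


_SAFE_LABEL = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-+")


def _quote_label(label: str | None) -> str:
    if label is None:
        return ""
    if label and all(c in _SAFE_LABEL for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"
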