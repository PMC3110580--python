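"""Rooted phylogenies: Newick I/O, branch-length transforms, node-age
interpolation, and the phylogenetic covariance matrix.

Trees are stored as a lightweight node structure.  Ages are measured in
time units before present (tips of an ultrametric tree sit at age 0) and a
branch length is the age difference between parent and child.  Newick
parsing and serialisation are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, List, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Phylogeny",
    "NewickError",
    "read_newick",
    "write_newick",
    "set_equal_branch_lengths",
    "interpolate_node_ages",
    "resolve_polytomies",
    "prune_to_tips",
    "phylo_covariance",
]

DEFAULT_ROOT_AGE = 139.0  # monocot-eudicot divergence, My


class NewickError(ValueError):
    """Malformed Newick input or invalid tree structure."""


class Node:
    """A node in a rooted tree.

    ``length`` is the branch length to the parent (``None`` for the root, or
    for a node whose input branch length was missing).  ``age`` is optional,
    in time units before present.
    """

    __slots__ = ("label", "length", "age", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None,
                 age: Optional[float] = None):
        self.label = label
        self.length = length
        self.age = age
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Phylogeny:
    """A rooted phylogeny with unique, non-empty tip labels."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> List[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_labels(self) -> List[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    # -- checks ------------------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for node in self.preorder():
            if node is not self.root and node.parent is None:
                raise NewickError("non-root node without a parent")
            if node.length is not None and node.length < 0:
                raise NewickError(
                    f"negative branch length {node.length} at {node.label!r}")
            if node.is_tip:
                if not node.label:
                    raise NewickError("tip with empty label")
                if node.label in seen:
                    raise NewickError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.internal_nodes())

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder()
                   if n is not self.root)

    def depths(self) -> Dict[int, float]:
        """Root-to-node path lengths keyed by ``id(node)``."""
        d: Dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise ValueError(f"missing branch length at {node.label!r}")
            d[id(node)] = d[id(node.parent)] + node.length
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()
        tip_depths = [d[id(t)] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) < tol

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder()
                   if n is not self.root)

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root), validate=False)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    else:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Missing branch lengths are kept as ``None`` (flagged, not zeroed).
    Raises :class:`NewickError` on malformed input or duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None  # a root edge length carries no information here
    try:
        return Phylogeny(root)
    except NewickError:
        raise


def write_newick(tree: Phylogeny, precision: int = 17) -> str:
    """Serialise a :class:`Phylogeny` to a one-line Newick string."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            body = _quote(node.label)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                body += _quote(node.label)
        if node.length is not None and node is not tree.root:
            body += f":{node.length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"


def _quote(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick_file(path) -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return read_newick(fh.read())


def write_newick_file(tree: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Branch-length manipulation
# ---------------------------------------------------------------------------

def set_equal_branch_lengths(tree: Phylogeny, value: float = 1.0) -> Phylogeny:
    """Return a copy with every branch length set to ``value``.

    Equalising branch lengths is the standard remedy when contrast
    diagnostics reject the original (dated) branch lengths.
    """
    if value <= 0:
        raise ValueError("branch length value must be positive")
    out = tree.copy()
    for node in out.preorder():
        if node is not out.root:
            node.length = float(value)
        node.age = None
    return out


def interpolate_node_ages(tree: Phylogeny,
                          fixed_ages: Optional[Dict[str, float]] = None,
                          root_age: Optional[float] = None) -> Phylogeny:
    """Assign ages to undated internal nodes by even spacing between dated
    nodes, then recompute branch lengths as age differences.

    ``fixed_ages`` maps node labels (internal-node names) to ages in time
    units before present; tips are fixed at age 0.  The root age must be
    supplied either through ``fixed_ages`` (by root label) or ``root_age``.
    Undated nodes on a path between two dated nodes are spaced evenly along
    that path (BLADJ-style), processed from the root downward so that each
    node is assigned exactly once, under the oldest available dated ancestor.
    """
    fixed_ages = dict(fixed_ages or {})
    out = tree.copy()

    for node in out.preorder():
        if node.is_tip:
            node.age = 0.0
        elif node.label is not None and node.label in fixed_ages:
            node.age = float(fixed_ages[node.label])
        else:
            node.age = None
    if out.root.age is None:
        if root_age is None:
            raise ValueError("root age must be fixed (fixed_ages or root_age)")
        out.root.age = float(root_age)

    # consistency: every dated descendant must be younger than its dated
    # ancestors
    def check(node: Node, ancestor_age: float) -> None:
        if node.age is not None:
            if node is not out.root and node.age >= ancestor_age:
                raise ValueError(
                    f"fixed age {node.age} at {node.label!r} is not younger "
                    f"than its dated ancestor ({ancestor_age})")
            ancestor_age = node.age
        for child in node.children:
            check(child, ancestor_age)

    check(out.root, np.inf)

    # BLADJ-style pass: for each still-undated node (preorder, so dated
    # ancestors are already resolved), find its nearest dated ancestor and
    # its nearest dated descendant, then age the whole chain between them
    # evenly.  Nearest descendant = fewest intervening nodes, ties broken by
    # the older age for conservatism, then label for determinism.
    for node in out.preorder():
        if node.age is not None:
            continue
        anc = node.parent
        while anc.age is None:  # root is always dated, loop terminates
            anc = anc.parent
        # BFS down for the nearest dated node, remembering the path
        best = None  # (depth, -age, label, path)
        frontier = [(node, [node])]
        depth = 0
        while best is None:
            depth += 1
            nxt = []
            for cur, path in frontier:
                for child in cur.children:
                    if child.age is not None:
                        key = (depth, -child.age, child.label or "")
                        if best is None or key < best[0]:
                            best = (key, path)
                    else:
                        nxt.append((child, path + [child]))
            frontier = nxt
        (_, neg_age, _), chain = best[0], best[1]
        desc_age = -neg_age
        # chain = undated nodes from `node` down toward the dated descendant
        step = (anc.age - desc_age) / (len(chain) + 1)
        for i, n in enumerate(chain, start=1):
            n.age = anc.age - i * step

    for node in out.preorder():
        if node is not out.root:
            node.length = node.parent.age - node.age
    return out


def resolve_polytomies(tree: Phylogeny, seed: int) -> Phylogeny:
    """Randomly resolve multifurcations with zero-length branches.

    Path lengths between all pre-existing nodes are unchanged, so the
    covariance structure of the tree is preserved; the resolution only fixes
    the pairing order used by the contrast recursion.  Deterministic for a
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.preorder()):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2,
                                     replace=False))
            a, b = node.children[i], node.children[j]
            merged = Node(label=None, length=0.0)
            node.children = [c for c in node.children if c is not a and c is not b]
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
    return out


def prune_to_tips(tree: Phylogeny, labels) -> Phylogeny:
    """Restrict the tree to a subset of tips, collapsing the unifurcations
    that pruning leaves behind (their branch lengths are summed)."""
    keep = set(labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")

    def prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            if node.label in keep:
                return Node(node.label, node.length, node.age)
            return None
        kept = [c2 for c2 in (prune(c) for c in node.children)
                if c2 is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(node.label, node.length, node.age)
        for c2 in kept:
            new.add_child(c2)
        return new

    root = prune(tree.root)
    if root is None or root.is_tip:
        raise ValueError("pruning would leave fewer than two tips")
    root.length = None
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------

def phylo_covariance(tree: Phylogeny) -> pd.DataFrame:
    """Brownian-motion covariance matrix among tips.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip distances.  Returned as a DataFrame
    indexed by tip label.
    """
    for node in tree.preorder():
        if node is not tree.root and (node.length is None or node.length < 0):
            raise ValueError("covariance needs non-negative branch lengths")
    tips = tree.tips()
    labels = [t.label for t in tips]
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(tips)
    depths = tree.depths()
    C = np.zeros((n, n))
    for t in tips:
        C[index[t.label], index[t.label]] = depths[id(t)]
    # postorder: tips in different child subtrees of a node share that
    # node's depth
    below: Dict[int, List[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = [node.label]
            continue
        groups = [below[id(c)] for c in node.children]
        d = depths[id(node)]
        for ga, gb in itertools.combinations(groups, 2):
            for la in ga:
                ia = index[la]
                for lb in gb:
                    ib = index[lb]
                    C[ia, ib] = d
                    C[ib, ia] = d
        below[id(node)] = [lab for g in groups for lab in g]
    return pd.DataFrame(C, index=labels, columns=labels)
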