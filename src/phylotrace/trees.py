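"""Lightweight phylogeny container and topological operations.

Trees are stored as rooted node structures.  Unrooted trees (``rooted=False``)
are kept *edge-rooted*: the root node has exactly two children and stands for
a point on the single edge between them, so an unrooted binary tree on n
leaves exposes the usual 2n-3 edges.  This makes Wagner-parsimony scoring a
plain postorder pass while leaving the unrooted semantics intact.

dendropy handles Newick serialization and is also used by the consensus
machinery in :mod:`phylotrace.stability`; everything topological that the
search engine needs (NNI/SPR surgery, splits, uniform random topologies) is
implemented directly on this structure.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

__all__ = ["Node", "Phylogeny"]


class Node:
    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '·'} ({len(self.children)} children)>"


class Phylogeny:
    """A rooted or unrooted phylogenetic tree with uniquely labeled leaves."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "Phylogeny":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        tree = cls._from_dendropy_node(dt.seed_node, rooted)
        if not rooted:
            tree._edge_root()
        return tree

    @classmethod
    def _from_dendropy_node(cls, seed, rooted: bool) -> "Phylogeny":
        def build(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            node = Node(label=label, length=dn.edge.length)
            for child in dn.child_nodes():
                node.add(build(child))
            return node

        root = build(seed)
        # collapse a unifurcating seed node
        while len(root.children) == 1:
            root = root.children[0]
            root.parent = None
        return cls(root, rooted=rooted)

    @classmethod
    def from_topology(cls, spec, rooted: bool = True) -> "Phylogeny":
        """Build from nested tuples/strings, e.g. ``(("A","B"),("C","D"))``."""

        def build(s) -> Node:
            if isinstance(s, str):
                return Node(label=s)
            node = Node()
            for sub in s:
                node.add(build(sub))
            return node

        tree = cls(build(spec), rooted=rooted)
        if not rooted:
            tree._edge_root()
        return tree

    def copy(self) -> "Phylogeny":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for child in node.children:
                new.add(dup(child))
            return new

        out = Phylogeny.__new__(Phylogeny)
        out.root = dup(self.root)
        out.rooted = self.rooted
        return out

    # -- invariants --------------------------------------------------------

    def _validate(self) -> None:
        labels = [leaf.label for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise ValueError("every leaf must carry a label")
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

    def _edge_root(self) -> None:
        """Normalize an unrooted tree to the edge-rooted representation."""
        if len(self.root.children) == 2 or self.root.is_leaf:
            return
        # pull the first child out and pair it against the rest
        first = self.root.children[0]
        rest = Node()
        for child in self.root.children[1:]:
            rest.add(child)
        new_root = Node()
        new_root.add(first)
        new_root.add(rest)
        if len(rest.children) == 1:  # degenerate (3-leaf star handled fine)
            only = rest.children[0]
            new_root.children[1] = only
            only.parent = new_root
        self.root = new_root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def edges(self) -> list[Node]:
        """Edges identified by their child node.

        For unrooted (edge-rooted) trees the two root-adjacent arcs stand for
        a single edge of the unrooted tree; only the first root child is
        reported, giving the expected 2n-3 edges.
        """
        out = []
        for node in self.preorder():
            if node is self.root:
                continue
            if not self.rooted and node.parent is self.root and node is self.root.children[1]:
                continue
            out.append(node)
        return out

    # -- topology fingerprints --------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions of the unrooted topology.

        Each split is canonicalized as the side *not* containing the
        lexicographically smallest leaf.
        """
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
                continue
            side = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = side
            if node is self.root or node.parent is self.root and not self.rooted:
                # root-adjacent arcs duplicate the root edge; the root side is trivial
                if node is self.root:
                    continue
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            canon = side if anchor not in side else all_leaves - side
            out.add(canon)
        return frozenset(out)

    def topology_key(self) -> frozenset:
        """Hashable identity of the unrooted topology (splits + leaf set)."""
        return frozenset([frozenset(self.leaf_labels()), self.splits()])

    def rf_distance(self, other: "Phylogeny") -> int:
        """Robinson–Foulds distance (symmetric difference of splits)."""
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            raise ValueError("trees must share a leaf set for RF distance")
        return len(self.splits() ^ other.splits())

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = _quote(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                core += f":{node.length:g}"
            return core

        root = self.root
        if not self.rooted and len(root.children) == 2 and not all(
            c.is_leaf for c in root.children
        ):
            # write the basal trifurcation customary for unrooted trees
            parts = []
            for child in root.children:
                if child.is_leaf:
                    parts.append(fmt(child))
                else:
                    parts.extend(fmt(g) for g in child.children)
            if len(parts) >= 3:
                return "(" + ",".join(parts) + ");"
        return fmt(root) + ";"

    def to_dendropy(
        self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None
    ) -> dendropy.Tree:
        tree = dendropy.Tree.get(
            data=self.to_newick(lengths=True),
            schema="newick",
            taxon_namespace=taxon_namespace,
        )
        tree.is_rooted = self.rooted
        return tree

    # -- surgery (used by the parsimony search) ----------------------------

    def prune_leaf(self, label: str) -> "Phylogeny":
        """Return a copy with one leaf removed (degree-2 nodes spliced out)."""
        out = self.copy()
        target = next((n for n in out.postorder() if n.is_leaf and n.label == label), None)
        if target is None:
            raise KeyError(f"no leaf labeled {label!r}")
        parent = target.parent
        if parent is None:
            raise ValueError("cannot prune the only node")
        parent.children.remove(target)
        _splice_unary(out, parent)
        return out

    def restrict(self, labels: Iterable[str]) -> "Phylogeny":
        """Induced topology on a leaf subset."""
        keep = set(labels)
        missing = keep - set(self.leaf_labels())
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        out = self
        for label in [l for l in self.leaf_labels() if l not in keep]:
            out = out.prune_leaf(label)
        return out

    def reroot_on_edge(self, child: Node) -> "Phylogeny":
        """Return a rooted copy with the root placed on the edge above `child`.

        `child` must be a node of *this* tree; positions are matched by a
        postorder index so the copy can be manipulated safely.
        """
        order = {id(n): i for i, n in enumerate(self.postorder())}
        idx = order.get(id(child))
        if idx is None:
            raise ValueError("node is not part of this tree")
        out = self.copy()
        target = list(out.postorder())[idx]
        if target.parent is None:
            raise ValueError("cannot root above the root placeholder")
        _reroot(out, target)
        out.rooted = True
        return out

    def unroot(self) -> "Phylogeny":
        out = self.copy()
        out.rooted = False
        out._edge_root()
        return out


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _splice_unary(tree: Phylogeny, node: Node) -> None:
    """Remove `node` if it has exactly one child, reconnecting around it."""
    if len(node.children) != 1:
        return
    only = node.children[0]
    if node.parent is None:
        only.parent = None
        tree.root = only
        # keep the edge-rooted shape for unrooted trees
        if not tree.rooted and len(only.children) > 2:
            tree._edge_root()
        return
    grand = node.parent
    pos = grand.children.index(node)
    grand.children[pos] = only
    only.parent = grand
    if only.length is not None and node.length is not None:
        only.length += node.length


def _reroot(tree: Phylogeny, child: Node) -> None:
    """Place a new degree-2 root on the edge above `child` (in place)."""
    old_parent = child.parent
    old_parent.children.remove(child)
    new_root = Node()
    new_root.add(child)
    # reverse parent pointers from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    # rebuild: old_parent becomes child of new_root, each former parent is
    # re-hung beneath its former child
    prev = new_root
    for i, node in enumerate(path):
        node.parent = None
        node.children = [c for c in node.children if c not in path[:i]]
        prev.add(node)
        prev = node
    # the old root is now a unary tail unless it kept >=2 children
    tree.root = new_root
    for node in reversed(path):
        _splice_unary(tree, node)


# -- topology generation and rearrangement ---------------------------------


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> Phylogeny:
    """Uniform random unrooted binary topology via sequential edge addition."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    order = list(rng.permutation(len(labels)))
    root = Node()
    root.add(Node(label=labels[order[0]]))
    root.add(Node(label=labels[order[1]]))
    tree = Phylogeny(root, rooted=False)
    for k in order[2:]:
        edges = tree.edges()
        # the root edge is a valid attachment point too: attaching to the
        # first root child is equivalent to attaching on the root edge
        target = edges[int(rng.integers(len(edges)))]
        attach_leaf(tree, target, labels[k])
    return tree


def attach_leaf(tree: Phylogeny, edge_child: Node, label: str) -> Node:
    """Insert a new leaf on the edge above `edge_child` (in place)."""
    parent = edge_child.parent
    mid = Node()
    pos = parent.children.index(edge_child)
    parent.children[pos] = mid
    mid.parent = parent
    mid.add(edge_child)
    return mid.add(Node(label=label))


def nni_neighbors(tree: Phylogeny) -> list[Phylogeny]:
    """All nearest-neighbor-interchange neighbors of an unrooted binary tree."""
    out = []
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}

    def swapped(a_idx: int, a_child: int, b_idx: int, b_child: int) -> Phylogeny:
        new = tree.copy()
        new_nodes = list(new.postorder())
        na, nb = new_nodes[a_idx], new_nodes[b_idx]
        ca, cb = na.children[a_child], nb.children[b_child]
        na.children[a_child], nb.children[b_child] = cb, ca
        ca.parent, cb.parent = nb, na
        return new

    root = tree.root
    r1, r2 = root.children
    if not r1.is_leaf and not r2.is_leaf:
        for j in range(2):
            out.append(swapped(index[id(r1)], 1, index[id(r2)], j))
    for v in nodes:
        if v.is_leaf or v is root or v.parent is root:
            continue
        u = v.parent
        sib_idx = 1 - u.children.index(v)
        for j in range(2):
            out.append(swapped(index[id(u)], sib_idx, index[id(v)], j))
    return out


def spr_neighbors(tree: Phylogeny, cap: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> list[Phylogeny]:
    """Subtree-prune-regraft neighbors of an unrooted binary tree.

    With `cap`, a random subset of (prune edge, regraft edge) pairs is drawn.
    """
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    pairs = []
    for v in nodes:
        if v is tree.root or v.parent is tree.root and len(tree.leaf_labels()) <= 4:
            continue
        if v.parent is None:
            continue
        forbidden = {id(n) for n in _subtree_nodes(v)}
        forbidden.add(id(v.parent))
        for e in tree.edges():
            if id(e) in forbidden or e is v:
                continue
            pairs.append((index[id(v)], index[id(e)]))
    if cap is not None and rng is not None and len(pairs) > cap:
        sel = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[int(i)] for i in sorted(sel)]
    out = []
    for v_idx, e_idx in pairs:
        new = tree.copy()
        new_nodes = list(new.postorder())
        v, e = new_nodes[v_idx], new_nodes[e_idx]
        if not _detach_subtree(new, v):
            continue
        if e.parent is None:  # regraft target vanished with the splice
            continue
        parent = e.parent
        mid = Node()
        pos = parent.children.index(e)
        parent.children[pos] = mid
        mid.parent = parent
        mid.add(e)
        mid.add(v)
        if set(new.leaf_labels()) == set(tree.leaf_labels()):
            out.append(new)
    return out


def _subtree_nodes(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _detach_subtree(tree: Phylogeny, node: Node) -> bool:
    parent = node.parent
    if parent is None:
        return False
    parent.children.remove(node)
    node.parent = None
    _splice_unary(tree, parent)
    return len(tree.leaf_labels()) >= 2
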