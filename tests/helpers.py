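"""Independent oracles shared by the test modules.

Everything here deliberately avoids the implementation paths it checks:
topologies are enumerated by recursive edge addition, Wagner lengths by
exhaustive assignment enumeration, quartet resolutions by split
containment, and patristic distances via dendropy.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from phylotrace.census import CharacterMatrix
from phylotrace.trees import Node, Phylogeny, attach_leaf


def all_topologies(labels):
    """Every unrooted binary topology on the labels (recursive addition)."""

    def rec(tree, rest):
        if not rest:
            yield tree
            return
        lab = rest[0]
        orig = list(tree.postorder())
        for edge in tree.edges():
            new = tree.copy()
            target = list(new.postorder())[orig.index(edge)]
            attach_leaf(new, target, lab)
            yield from rec(new, rest[1:])

    root = Node()
    root.add(Node(label=labels[0]))
    root.add(Node(label=labels[1]))
    yield from rec(Phylogeny(root, rooted=False), list(labels[2:]))


def brute_force_wagner(matrix: CharacterMatrix, tree: Phylogeny) -> int:
    """Minimum ordered-character steps by enumerating internal assignments."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    states = {t: matrix.states[i] for i, t in enumerate(matrix.taxa)}
    total = 0
    for j in range(matrix.states.shape[1]):
        smax = int(matrix.states[:, j].max())
        best = None
        for assign in itertools.product(range(smax + 1), repeat=len(internals)):
            amap = {id(n): a for n, a in zip(internals, assign)}
            cost = 0
            for n in nodes:
                if n.parent is None:
                    continue
                sv = states[n.label][j] if n.is_leaf else amap[id(n)]
                cost += abs(int(sv) - amap[id(n.parent)])
            if best is None or cost < best:
                best = cost
        total += best
    return total


def quartet_type_by_splits(tree: Phylogeny, a, b, c, d):
    """Quartet resolution from bipartitions: 0=ab|cd, 1=ac|bd, 2=ad|bc, -1."""
    quartet = {a, b, c, d}
    pairings = [({a, b}, {c, d}), ({a, c}, {b, d}), ({a, d}, {b, c})]
    all_leaves = frozenset(tree.leaf_labels())
    for split in tree.splits():
        other = all_leaves - split
        for k, (p1, p2) in enumerate(pairings):
            if (p1 <= split and p2 <= other) or (p1 <= other and p2 <= split):
                return k
    return -1


def dendropy_node_distances(tree: Phylogeny):
    """Pairwise node-count leaf distances via dendropy (unit edge lengths)."""
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    for edge in dt.preorder_edge_iter():
        edge.length = 1.0
    pdm = dt.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in dt.taxon_namespace)
    lookup = {t.label: t for t in dt.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if i != j:
                out[i, j] = pdm.path_edge_count(lookup[li], lookup[lj])
    return labels, out


def group_monophyly(tree: Phylogeny, groups: dict) -> dict:
    """Whether each group's taxa form a clade of the unrooted topology."""
    splits = tree.splits()
    allt = frozenset(tree.leaf_labels())
    anchor = min(allt)
    out = {}
    for g in sorted(set(groups.values())):
        tg = frozenset(t for t in allt if groups[t] == g)
        if len(tg) in (0, 1) or len(allt - tg) <= 1:
            out[g] = True
            continue
        canon = tg if anchor not in tg else allt - tg
        out[g] = canon in splits
    return out
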