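"""Bootstrap tree sets and quartet-based stability diagnostics.

In unrooted trees the smallest phylogenetic statement is a quartet of
leaves.  Leaf stability (LS) summarizes, for every leaf, how consistently
the quartets containing it resolve across a set of bootstrap trees; the
Explicitly-Agree (EA) similarity compares the quartets of two trees; and the
taxon instability index (TII) measures the variability of a leaf's patristic
distances to all other leaves across the tree set.  Rogue taxa -- leaves
that wander among replicates and erode consensus support -- are flagged by a
greedy leaf-dropping criterion that maximizes the (normalized) total support
of the majority-rule consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from phylotrace.census import CharacterMatrix
from phylotrace.trees import Phylogeny

__all__ = [
    "TreeSet",
    "StabilityReport",
    "bootstrap_trees",
    "consensus",
    "leaf_stability",
    "explicitly_agree",
    "taxon_instability",
    "detect_rogues",
    "stability_report",
]


@dataclass
class TreeSet:
    """Unrooted trees on a common leaf set (e.g., bootstrap replicates)."""

    trees: list[Phylogeny]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a TreeSet needs at least one tree")
        leafset = set(self.trees[0].leaf_labels())
        for t in self.trees[1:]:
            if set(t.leaf_labels()) != leafset:
                raise ValueError("all trees in a TreeSet must share a leaf set")

    @property
    def labels(self) -> list[str]:
        return sorted(self.trees[0].leaf_labels())

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class StabilityReport:
    """Per-leaf stability table plus the conventions used to compute it."""

    table: pd.DataFrame  # leaf, group?, ls_max, ls_difference, ls_entropy, ea?, tii
    metadata: dict = field(default_factory=dict)


def bootstrap_trees(
    matrix: CharacterMatrix,
    n_reps: int,
    seed: int = 0,
    search_params: Optional[dict] = None,
) -> TreeSet:
    """Character-resampled bootstrap: one best tree per replicate."""
    from phylotrace.parsimony import search

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    # max_trees > 1 so equally-parsimonious sets are enumerated and the
    # "first by deterministic tie order" contract holds across replicates
    params = {"strategy": "SPR", "n_starts": 1, "max_trees": 8}
    params.update(search_params or {})
    rng = np.random.default_rng(seed)
    trees = []
    for rep in range(n_reps):
        replicate = matrix.resample_characters(rng)
        sub_seed = int(rng.integers(2**31 - 1))
        best, _ = search(replicate, seed=sub_seed, **params)
        trees.append(best[0])  # deterministic first-by-newick tie order
    return TreeSet(trees=trees, provenance={"n_reps": n_reps, "seed": seed, **params})


def consensus(trees: TreeSet, kind: str = "strict") -> Phylogeny:
    """Strict or majority-rule consensus (bipartition-based, via dendropy)."""
    if kind not in ("strict", "majority"):
        raise ValueError("kind must be 'strict' or 'majority'")
    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for t in trees.trees:
        tl.append(t.to_dendropy(taxon_namespace=ns))
    min_freq = 1.0 if kind == "strict" else 0.5
    cons = tl.consensus(min_freq=min_freq)
    out = Phylogeny._from_dendropy_node(cons.seed_node, rooted=False)
    return out


def _split_frequencies(trees: Sequence[Phylogeny]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    return {s: c / n for s, c in counts.items()}


# -- quartets --------------------------------------------------------------


def _leaf_distance_matrix(tree: Phylogeny, labels: Sequence[str],
                          use_lengths: bool = False) -> np.ndarray:
    """Pairwise leaf distances (node count by default; branch steps if asked)."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adj: dict[int, list[tuple[int, float]]] = {}

    def w(node) -> float:
        if use_lengths and node.length is not None:
            return float(node.length)
        return 1.0

    nodes = list(tree.postorder())
    root = tree.root
    bypass_root = len(root.children) == 2  # virtual edge point, not a node
    for node in nodes:
        for child in node.children:
            if bypass_root and node is root:
                continue
            adj.setdefault(id(node), []).append((id(child), w(child)))
            adj.setdefault(id(child), []).append((id(node), w(child)))
    if bypass_root:
        c1, c2 = root.children
        weight = (c1.length or 0.0) + (c2.length or 0.0) if use_lengths else 1.0
        if use_lengths and c1.length is None and c2.length is None:
            weight = 1.0
        adj.setdefault(id(c1), []).append((id(c2), weight))
        adj.setdefault(id(c2), []).append((id(c1), weight))
    leaf_ids = {id(n): n.label for n in nodes if n.is_leaf}
    dist = np.zeros((n, n))
    for nid, label in leaf_ids.items():
        # Dijkstra is overkill on trees; BFS with accumulated weights
        seen = {nid: 0.0}
        stack = [nid]
        while stack:
            cur = stack.pop()
            for nxt, wt in adj.get(cur, ()):
                if nxt not in seen:
                    seen[nxt] = seen[cur] + wt
                    stack.append(nxt)
        for other_id, other_label in leaf_ids.items():
            dist[index[label], index[other_label]] = seen[other_id]
    return dist


def _quartet_type(dist: np.ndarray, a: int, b: int, c: int, d: int) -> int:
    """Resolution of quartet {a,b,c,d}: 0=ab|cd, 1=ac|bd, 2=ad|bc, -1 unresolved."""
    s = (
        dist[a, b] + dist[c, d],
        dist[a, c] + dist[b, d],
        dist[a, d] + dist[b, c],
    )
    m = min(s)
    winners = [i for i, v in enumerate(s) if v == m]
    return winners[0] if len(winners) == 1 else -1


def _quartet_frequencies(
    treeset: TreeSet, quartets: Sequence[tuple[int, int, int, int]]
) -> dict[tuple, np.ndarray]:
    labels = treeset.labels
    mats = [_leaf_distance_matrix(t, labels) for t in treeset.trees]
    freqs = {}
    for q in quartets:
        counts = np.zeros(3)
        for dist in mats:
            t = _quartet_type(dist, *q)
            if t >= 0:
                counts[t] += 1
        freqs[q] = counts
    return freqs


def _ls_score(counts: np.ndarray, variant: str) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0  # quartet resolved in no tree
    f = np.sort(counts / total)[::-1]
    if variant == "max":
        return float(f[0])
    if variant == "difference":
        return float(f[0] - f[1])
    if variant == "entropy":
        nz = f[f > 0]
        h = -(nz * np.log(nz)).sum()
        return float(1.0 - h / np.log(3.0))
    raise ValueError("variant must be 'max', 'difference', or 'entropy'")


def leaf_stability(
    trees: TreeSet,
    variant: str = "max",
    quartet_cap: Optional[int] = None,
    seed: int = 0,
) -> pd.Series:
    """Mean quartet-support score per leaf over the quartets containing it.

    For each quartet the three resolution frequencies f1 >= f2 >= f3 are
    taken over the trees that resolve it; the per-quartet score is f1
    ("max"), f1 - f2 ("difference"), or 1 - H(f)/log 3 ("entropy").  With a
    `quartet_cap`, quartets per leaf are subsampled (seeded).
    """
    if len(trees) < 2:
        raise ValueError("leaf stability needs at least 2 trees")
    labels = trees.labels
    n = len(labels)
    if n < 4:
        raise ValueError("leaf stability needs at least 4 leaves")
    rng = np.random.default_rng(seed)
    per_leaf_quartets: dict[int, list[tuple]] = {}
    all_quartets = list(combinations(range(n), 4))
    if quartet_cap is None or len(all_quartets) * 4 // n <= quartet_cap:
        for q in all_quartets:
            for leaf in q:
                per_leaf_quartets.setdefault(leaf, []).append(q)
    else:
        for leaf in range(n):
            others = [i for i in range(n) if i != leaf]
            pool = list(combinations(others, 3))
            if len(pool) > quartet_cap:
                sel = rng.choice(len(pool), size=quartet_cap, replace=False)
                pool = [pool[int(i)] for i in sorted(sel)]
            per_leaf_quartets[leaf] = [tuple(sorted((leaf,) + trio)) for trio in pool]
    needed = sorted({q for qs in per_leaf_quartets.values() for q in qs})
    freqs = _quartet_frequencies(trees, needed)
    out = {}
    for leaf, qs in per_leaf_quartets.items():
        scores = [_ls_score(freqs[q], variant) for q in qs]
        out[labels[leaf]] = float(np.mean(scores)) if scores else 0.0
    return pd.Series(out).sort_index()


def explicitly_agree(tree_a: Phylogeny, tree_b: Phylogeny) -> pd.Series:
    """Per-leaf fraction of its quartets resolved identically in both trees."""
    labels = sorted(tree_a.leaf_labels())
    if set(labels) != set(tree_b.leaf_labels()):
        raise ValueError("trees must share a leaf set")
    n = len(labels)
    if n < 4:
        raise ValueError("EA needs at least 4 leaves")
    da = _leaf_distance_matrix(tree_a, labels)
    db = _leaf_distance_matrix(tree_b, labels)
    agree = np.zeros(n)
    totals = np.zeros(n)
    for q in combinations(range(n), 4):
        ta = _quartet_type(da, *q)
        tb = _quartet_type(db, *q)
        same = ta >= 0 and ta == tb
        for leaf in q:
            totals[leaf] += 1
            if same:
                agree[leaf] += 1
    return pd.Series(agree / totals, index=labels)


def taxon_instability(trees: TreeSet, distance: str = "node_count") -> pd.Series:
    """Mesquite-style TII: summed relative variation of patristic distances.

    TII(t) = sum over unordered tree pairs (x, y) and other leaves l of
    |D_x(t,l) - D_y(t,l)| / (D_x(t,l) + D_y(t,l))^2.  Zero iff the leaf's
    patristic profile is constant across trees.
    """
    if len(trees) < 2:
        raise ValueError("TII needs at least 2 trees")
    if distance not in ("node_count", "steps"):
        raise ValueError("distance must be 'node_count' or 'steps'")
    labels = trees.labels
    mats = np.array(
        [
            _leaf_distance_matrix(t, labels, use_lengths=(distance == "steps"))
            for t in trees.trees
        ]
    )
    n = len(labels)
    tii = np.zeros(n)
    for x, y in combinations(range(len(trees)), 2):
        dx, dy = mats[x], mats[y]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.abs(dx - dy) / np.square(dx + dy)
        np.fill_diagonal(contrib, 0.0)
        contrib = np.nan_to_num(contrib)
        tii += contrib.sum(axis=1)
    return pd.Series(tii, index=labels)


def _consensus_support_score(trees: Sequence[Phylogeny]) -> float:
    """Normalized sum of majority-rule bipartition frequencies (RBIC-like)."""
    n_leaves = len(trees[0].leaf_labels())
    if n_leaves < 4:
        return 1.0
    freqs = _split_frequencies(trees)
    majority = [f for f in freqs.values() if f > 0.5]
    return float(sum(majority)) / (n_leaves - 3)


def detect_rogues(
    trees: TreeSet, max_drop: int = 3, threshold: float = 0.0
) -> list[str]:
    """Greedy rogue-taxon detection (simplified RogueNaRok-style RBIC).

    Iteratively drops the leaf whose removal most increases the normalized
    majority-consensus support, while the relative improvement exceeds the
    threshold.  Deterministic tie-break by label.  Not identical to
    RogueNaRok's exact RBIC optimization.
    """
    if len(trees) < 2:
        raise ValueError("rogue detection needs at least 2 trees")
    current = list(trees.trees)
    labels = sorted(current[0].leaf_labels())
    rogues: list[str] = []
    score = _consensus_support_score(current)
    while len(rogues) < max_drop and len(labels) > 4:
        best = None
        for leaf in labels:
            pruned = [t.prune_leaf(leaf) for t in current]
            s = _consensus_support_score(pruned)
            if best is None or s > best[1] or (s == best[1] and leaf < best[0]):
                best = (leaf, s, pruned)
        improvement = best[1] - score
        rel = improvement / score if score > 0 else improvement
        if rel <= threshold:
            break
        rogues.append(best[0])
        labels.remove(best[0])
        current = best[2]
        score = best[1]
    return rogues


def stability_report(
    trees: TreeSet,
    groups: Optional[dict] = None,
    quartet_cap: Optional[int] = None,
    seed: int = 0,
    distance: str = "node_count",
    max_drop: int = 3,
) -> StabilityReport:
    """Combined per-leaf LS (all variants), TII, and rogue ranking."""
    ls = {
        f"ls_{v}": leaf_stability(trees, variant=v, quartet_cap=quartet_cap, seed=seed)
        for v in ("max", "difference", "entropy")
    }
    tii = taxon_instability(trees, distance=distance)
    rogues = detect_rogues(trees, max_drop=max_drop)
    table = pd.DataFrame({**ls, "tii": tii})
    table.index.name = "leaf"
    table["rogue_rank"] = [
        rogues.index(leaf) + 1 if leaf in rogues else 0 for leaf in table.index
    ]
    if groups:
        table.insert(0, "group", [groups.get(leaf, "?") for leaf in table.index])
    meta = {
        "n_trees": len(trees),
        "quartet_normalization": "over trees resolving the quartet; never-resolved quartets score 0",
        "tii_distance": distance,
        "rogue_criterion": "greedy RBIC-like, normalized by (n_leaves - 3)",
    }
    return StabilityReport(table=table, metadata=meta)
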