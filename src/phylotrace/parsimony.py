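"""Wagner (ordered/additive) maximum parsimony and a-posteriori rooting.

Characters are ordered multistate: the cost of a change between states a and
b is |a - b|.  Tree length is computed exactly with the Farris interval
algorithm (a postorder pass that carries, per character, the closed interval
of optimal states at each node), vectorized over characters with numpy.
Trees are optimized *unrooted* -- length is invariant to root position -- and
rooted only afterwards with the Lundberg method: a hypothetical ancestral
state vector (all-minimum or all-maximum states, the two polarizations of
ordered characters) is attached in turn to every branch and the attachment
adding the fewest steps becomes the root.  Under Weston's generality
criterion the winning polarization is decided empirically as the one giving
the shorter rooted tree; ties go to the all-minimum vector and are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from phylotrace.census import CharacterMatrix
from phylotrace.trees import (
    Node,
    Phylogeny,
    attach_leaf,
    nni_neighbors,
    random_topology,
    spr_neighbors,
)

__all__ = [
    "TreeScore",
    "RootingResult",
    "wagner_length",
    "search",
    "lundberg_root",
    "inverse_polarization_check",
    "retention_index",
    "farris_f",
    "g1_statistic",
    "tally_gains_losses",
]


@dataclass
class TreeScore:
    length: int
    branch_lengths: dict = field(default_factory=dict)
    retention_index: Optional[float] = None
    farris_f: Optional[float] = None
    g1: Optional[float] = None


@dataclass
class RootingResult:
    tree: Phylogeny  # rooted
    polarization: str  # "min" or "max"
    rooted_lengths: dict  # polarization -> rooted length (incl. ancestor steps)
    attachment_costs: dict  # polarization -> added steps at the chosen branch
    tie: bool = False


def _check_leaves(matrix: CharacterMatrix, tree: Phylogeny) -> None:
    mt, tt = set(matrix.taxa), set(tree.leaf_labels())
    if mt != tt:
        raise ValueError(
            "matrix/tree taxon mismatch; only in matrix: "
            f"{sorted(mt - tt)}, only in tree: {sorted(tt - mt)}"
        )


def _intervals(tree: Phylogeny, states: dict[str, np.ndarray]):
    """Farris interval pass. Returns (cost array, {node id -> (low, high)})."""
    low: dict[int, np.ndarray] = {}
    high: dict[int, np.ndarray] = {}
    n_chars = next(iter(states.values())).shape[0] if states else 0
    cost = np.zeros(n_chars, dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            s = states[node.label]
            low[id(node)] = s
            high[id(node)] = s
            continue
        if len(node.children) != 2:
            raise ValueError("Wagner scoring requires a binary (edge-rooted) tree")
        c1, c2 = node.children
        l1, h1 = low[id(c1)], high[id(c1)]
        l2, h2 = low[id(c2)], high[id(c2)]
        inter_low = np.maximum(l1, l2)
        inter_high = np.minimum(h1, h2)
        gap = inter_low - inter_high  # > 0 where the intervals are disjoint
        disjoint = gap > 0
        cost += np.where(disjoint, gap, 0)
        low[id(node)] = np.where(disjoint, inter_high, inter_low)
        high[id(node)] = np.where(disjoint, inter_low, inter_high)
    return cost, low, high


def _states_by_label(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    return {t: matrix.states[i] for i, t in enumerate(matrix.taxa)}


def _minimal_assignment(tree: Phylogeny, states: dict[str, np.ndarray],
                        root_policy: str = "min") -> dict[int, np.ndarray]:
    """One minimal Wagner assignment (preorder clamp into Farris intervals).

    The root takes the minimal-state endpoint of its interval (``root_policy
    = "min"``, the deterministic tie-break used for gain/loss tallies) or the
    maximal endpoint (``"max"``).
    """
    _, low, high = _intervals(tree, states)
    assign: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            assign[id(node)] = low[id(node)] if root_policy == "min" else high[id(node)]
        else:
            p = assign[id(node.parent)]
            assign[id(node)] = np.clip(p, low[id(node)], high[id(node)])
    return assign


def wagner_length(matrix: CharacterMatrix, tree: Phylogeny) -> TreeScore:
    """Exact minimum number of ordered-character steps on a tree.

    Branch lengths come from one minimal assignment (root clamped to the
    interval minimum); their sum equals the tree length.
    """
    _check_leaves(matrix, tree)
    states = _states_by_label(matrix)
    cost, _, _ = _intervals(tree, states)
    assign = _minimal_assignment(tree, states)
    branch_lengths = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        diff = np.abs(assign[id(node)] - assign[id(node.parent)]).sum()
        branch_lengths[id(node)] = int(diff)
    return TreeScore(length=int(cost.sum()), branch_lengths=branch_lengths)


def tree_length(matrix: CharacterMatrix, tree: Phylogeny) -> int:
    """Length only (no assignment pass); used in search inner loops."""
    states = _states_by_label(matrix)
    cost, _, _ = _intervals(tree, states)
    return int(cost.sum())


# -- heuristic search ------------------------------------------------------


def _greedy_addition(matrix: CharacterMatrix, order: Sequence[str]) -> Phylogeny:
    """Random-addition-sequence starting tree (greedy Wagner addition)."""
    states = _states_by_label(matrix)
    root = Node()
    root.add(Node(label=order[0]))
    root.add(Node(label=order[1]))
    tree = Phylogeny(root, rooted=False)
    for label in order[2:]:
        best = None
        for k, edge in enumerate(list(tree.edges())):
            trial = tree.copy()
            trial_edge = list(trial.postorder())
            orig = list(tree.postorder())
            target = trial_edge[orig.index(edge)]
            attach_leaf(trial, target, label)
            cost, _, _ = _intervals(trial, states)
            length = int(cost.sum())
            if best is None or length < best[0]:
                best = (length, trial)
        tree = best[1]
    return tree


def search(
    matrix: CharacterMatrix,
    strategy: str = "SPR",
    n_starts: int = 5,
    seed: int = 0,
    max_trees: int = 100,
) -> tuple[list[Phylogeny], TreeScore]:
    """Heuristic maximum-parsimony search over unrooted binary topologies.

    Random-addition starts followed by steepest-descent hill climbing with
    NNI, SPR, or TBR rearrangements (TBR is realized as SPR moves compounded
    with an NNI sweep).  All distinct equally-best topologies encountered on
    the final plateau are returned (capped at ``max_trees``), in a
    deterministic order given the seed.
    """
    if len(matrix.taxa) < 4:
        raise ValueError("search requires at least 4 taxa")
    strategy = strategy.upper()
    if strategy not in ("NNI", "SPR", "TBR"):
        raise ValueError("strategy must be one of NNI, SPR, TBR")
    rng = np.random.default_rng(seed)
    states = _states_by_label(matrix)

    def score(tree: Phylogeny) -> int:
        cost, _, _ = _intervals(tree, states)
        return int(cost.sum())

    def neighbors(tree: Phylogeny) -> list[Phylogeny]:
        if strategy == "NNI":
            return nni_neighbors(tree)
        moves = spr_neighbors(tree)
        if strategy == "TBR":
            moves = moves + nni_neighbors(tree)
        return moves

    best_len: Optional[int] = None
    best: dict[frozenset, Phylogeny] = {}

    plateau_budget = 2 * len(matrix.taxa)
    for _ in range(n_starts):
        order = [matrix.taxa[i] for i in rng.permutation(len(matrix.taxa))]
        tree = _greedy_addition(matrix, order)
        current = score(tree)
        visited = {tree.topology_key()}
        plateau_left = plateau_budget
        while True:
            candidates = sorted(
                ((score(nb), nb.to_newick(), nb) for nb in neighbors(tree)),
                key=lambda t: (t[0], t[1]),
            )
            if not candidates:
                break
            if candidates[0][0] < current:
                current, _, tree = candidates[0]
                visited.add(tree.topology_key())
                plateau_left = plateau_budget
                continue
            # sideways moves escape flat regions of the length landscape
            stepped = False
            if plateau_left > 0:
                for length, _, nb in candidates:
                    if length > current:
                        break
                    key = nb.topology_key()
                    if key not in visited:
                        tree = nb
                        visited.add(key)
                        plateau_left -= 1
                        stepped = True
                        break
            if not stepped:
                break
        if best_len is None or current < best_len:
            best_len = current
            best = {}
        if current == best_len:
            best.setdefault(tree.topology_key(), tree)

    # plateau sweep: collect equally-parsimonious neighbors of the optima
    frontier = list(best.values())
    while frontier and len(best) < max_trees:
        tree = frontier.pop()
        for nb in neighbors(tree):
            if len(best) >= max_trees:
                break
            if score(nb) == best_len:
                key = nb.topology_key()
                if key not in best:
                    best[key] = nb
                    frontier.append(nb)

    ordered = sorted(best.values(), key=lambda t: t.to_newick())
    return ordered, TreeScore(length=best_len)


# -- rooting ---------------------------------------------------------------

_ANCESTOR_LABEL = "__lundberg_ancestor__"


def _attachment_costs(matrix: CharacterMatrix, tree: Phylogeny, alpha: int):
    """Added steps for attaching a constant-state ancestor on each edge."""
    states = dict(_states_by_label(matrix))
    n_chars = len(matrix.characters)
    states[_ANCESTOR_LABEL] = np.full(n_chars, alpha, dtype=np.int64)
    base, _, _ = _intervals(tree, _states_by_label(matrix))
    base_len = int(base.sum())
    costs = []
    orig_nodes = list(tree.postorder())
    for edge in tree.edges():
        trial = tree.copy()
        target = list(trial.postorder())[orig_nodes.index(edge)]
        attach_leaf(trial, target, _ANCESTOR_LABEL)
        cost, _, _ = _intervals(trial, states)
        costs.append(int(cost.sum()) - base_len)
    return base_len, costs


def lundberg_root(matrix: CharacterMatrix, tree: Phylogeny) -> RootingResult:
    """Root an optimized unrooted tree a posteriori (Lundberg method).

    Both polarizations of the ordered characters are tried: an all-minimum
    (state 0) and an all-maximum (state S-1) hypothetical ancestor.  Each is
    attached to every branch; the cheapest attachment of the polarization
    with the smaller total rooted length places the root.  The ingroup
    topology is never altered.
    """
    _check_leaves(matrix, tree)
    unrooted = tree if not tree.rooted else tree.unroot()
    results = {}
    for name, alpha in (("min", 0), ("max", matrix.n_states - 1)):
        base_len, costs = _attachment_costs(matrix, unrooted, alpha)
        k = int(np.argmin(costs))
        results[name] = (base_len + costs[k], costs[k], k)
    tie = results["min"][0] == results["max"][0]
    winner = "min" if results["min"][0] <= results["max"][0] else "max"
    edge = unrooted.edges()[results[winner][2]]
    rooted = unrooted.reroot_on_edge(edge)
    return RootingResult(
        tree=rooted,
        polarization=winner,
        rooted_lengths={p: results[p][0] for p in results},
        attachment_costs={p: results[p][1] for p in results},
        tie=tie,
    )


def inverse_polarization_check(matrix: CharacterMatrix, tree: Phylogeny) -> dict:
    """Compare the optimal polarization with its inverse (always >=)."""
    res = lundberg_root(matrix, tree)
    loser = "max" if res.polarization == "min" else "min"
    margin = res.rooted_lengths[loser] - res.rooted_lengths[res.polarization]
    return {
        "optimal_polarization": res.polarization,
        "optimal_length": res.rooted_lengths[res.polarization],
        "suboptimal_length": res.rooted_lengths[loser],
        "margin": int(margin),
        "suboptimal_is_longer_or_equal": margin >= 0,
    }


# -- fit diagnostics -------------------------------------------------------


def character_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (m_j, g_j): range lower bound and star-tree upper bound."""
    s = matrix.states
    m = s.max(axis=0) - s.min(axis=0)
    med = np.median(s, axis=0)
    # integer medians minimize sum |s - a| over integer a for ordered states
    g = np.abs(s - np.floor(med)[None, :]).sum(axis=0)
    g_alt = np.abs(s - np.ceil(med)[None, :]).sum(axis=0)
    return m.astype(np.int64), np.minimum(g, g_alt).astype(np.int64)


def retention_index(matrix: CharacterMatrix, tree: Phylogeny) -> Optional[float]:
    """RI = (G - L) / (G - M); None when every character has G_j == M_j."""
    _check_leaves(matrix, tree)
    m, g = character_bounds(matrix)
    L = tree_length(matrix, tree)
    G, M = int(g.sum()), int(m.sum())
    if G == M:
        return None
    return (G - L) / (G - M)


def farris_f(matrix: CharacterMatrix, tree: Phylogeny) -> float:
    """Farris's f: total excess of patristic over original (L1) distances.

    Patristic distances come from the branch lengths of one minimal Wagner
    assignment, so every pairwise term is non-negative.
    """
    _check_leaves(matrix, tree)
    states = _states_by_label(matrix)
    assign = _minimal_assignment(tree, states)
    # per-leaf path profile: accumulate branch lengths from root
    depth: dict[int, float] = {id(tree.root): 0.0}
    leaf_depth = {}
    paths: dict[int, list[int]] = {id(tree.root): []}
    leaf_path = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        step = int(np.abs(assign[id(node)] - assign[id(node.parent)]).sum())
        depth[id(node)] = depth[id(node.parent)] + step
        paths[id(node)] = paths[id(node.parent)] + [id(node)]
        if node.is_leaf:
            leaf_depth[node.label] = depth[id(node)]
            leaf_path[node.label] = paths[id(node)]
    lengths = {}
    for node in tree.preorder():
        if node.parent is not None:
            lengths[id(node)] = int(
                np.abs(assign[id(node)] - assign[id(node.parent)]).sum()
            )
    total = 0.0
    for a, b in combinations(sorted(leaf_path), 2):
        pa, pb = leaf_path[a], leaf_path[b]
        shared = 0
        for x, y in zip(pa, pb):
            if x == y:
                shared += lengths[x]
            else:
                break
        p = leaf_depth[a] + leaf_depth[b] - 2 * shared
        d = int(np.abs(states[a] - states[b]).sum())
        total += p - d
    return total


def g1_statistic(
    matrix: CharacterMatrix, n_random_trees: int = 1000, seed: int = 0
) -> Optional[float]:
    """Skewness of Wagner tree lengths over uniform random topologies.

    Strongly negative values indicate phylogenetic structure.  Returns None
    when the length distribution is degenerate (zero variance).
    """
    if n_random_trees < 100:
        raise ValueError("n_random_trees must be at least 100")
    rng = np.random.default_rng(seed)
    states = _states_by_label(matrix)
    lengths = np.empty(n_random_trees)
    for i in range(n_random_trees):
        tree = random_topology(matrix.taxa, rng)
        cost, _, _ = _intervals(tree, states)
        lengths[i] = cost.sum()
    if np.ptp(lengths) == 0:
        return None
    return float(stats.skew(lengths, bias=True))


def tally_gains_losses(
    matrix: CharacterMatrix, tree: Phylogeny, polarization: str = "min"
) -> dict:
    """Sum state increments (gains) and decrements (losses) along branches.

    Requires a rooted tree; ancestral states come from one minimal Wagner
    assignment with the root clamped toward the ancestral polarization
    (interval minimum for "min", maximum for "max").  gains + losses equals
    the tree length.
    """
    if not tree.rooted:
        raise ValueError("gain/loss tallies require a rooted tree")
    _check_leaves(matrix, tree)
    states = _states_by_label(matrix)
    assign = _minimal_assignment(tree, states, root_policy=polarization)
    gains = losses = 0
    per_branch = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        delta = assign[id(node)] - assign[id(node.parent)]
        g = int(delta[delta > 0].sum())
        l = int(-delta[delta < 0].sum())
        gains += g
        losses += l
        label = node.label or f"node{id(node) % 10000}"
        per_branch[label] = (g, l)
    return {
        "gains": gains,
        "losses": losses,
        "length": gains + losses,
        "per_branch": per_branch,
        "polarization": polarization,
    }
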