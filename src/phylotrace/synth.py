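"""Synthetic FSF-census generators with known ground truth.

The generator emulates the statistical structure of real proteome censuses:
four supergroups (Viruses, Archaea, Bacteria, Eukarya) each following its
own Heaps-law regime relating vocabulary (FSF use, V) to database size (FSF
reuse, N) via V ~ c * N^beta with lognormal scatter; a shared ancient
"kernel" of universal FSFs carried by every taxon (and assigned node-
distance ages near 0); group-specific FSF blocks that give parsimony a clean
monophyly signal; a shared extra pool whose per-taxon draws create
overlapping use/reuse clouds across groups; within-group phylogenetic
autocorrelation from a Brownian walk of log-abundance weights along a Yule
tree; and optional extreme-reduced "rogue" taxa with randomized composition.

Default regime exponents are 0.81 (V), 0.36 (A), 0.19 (B) and 0.03 (E) --
the universal-FSF scaling the pipeline is designed to recover -- with
log-uniform reuse ranges that overlap between neighboring groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from phylotrace.census import CensusMatrix
from phylotrace.trees import Node, Phylogeny, attach_leaf, random_topology

__all__ = [
    "AccretionConfig",
    "GeneratorConfig",
    "generate_accretion_census",
    "GroundTruth",
    "generate_census",
    "generate_tree_set",
    "ancestor_profile",
    "yule_tree",
]

GROUP_ORDER = ("V", "A", "B", "E")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic census.

    Per-group Heaps exponents are the universal-FSF regime values the
    pipeline fits; reuse ranges are log-uniform and overlap between
    neighboring groups; `heaps_c` prefactors keep vocabularies inside the
    available FSF pool.
    """

    seed: int
    n_taxa: dict = field(default_factory=lambda: {"V": 4, "A": 4, "B": 4, "E": 4})
    beta: dict = field(default_factory=lambda: {"V": 0.81, "A": 0.36, "B": 0.19, "E": 0.03})
    reuse_range: dict = field(
        default_factory=lambda: {
            "V": (100, 1000),
            "A": (800, 8000),
            "B": (1500, 20000),
            "E": (3000, 50000),
        }
    )
    heaps_c: dict = field(default_factory=lambda: {"V": 0.30, "A": 4.5, "B": 14.0, "E": 90.0})
    zipf_gamma: dict = field(default_factory=lambda: {"V": 1.25, "A": 1.5, "B": 2.0, "E": 1.4})
    sigma_v: float = 0.05  # lognormal scatter of vocabulary around the power law
    kernel_size: int = 60
    group_specific_n: int = 30
    shared_extra_n: int = 90
    bm_sigma: float = 0.3  # Brownian noise of log-abundance weights per unit time
    rank_jitter: float = 6.0  # per-taxon scatter of composition ranks
    profile_sigma: float = 15.0  # per-group preference offset on composition ranks
    profile_logw_sigma: float = 1.5  # per-group log-abundance profile over FSFs
    min_branch: float = 0.0  # floor on Yule branch lengths (signal per edge)
    size_by_tree: bool = False  # assign proteome sizes along the group tree
    #   (phylogenetically autocorrelated size, as in real lineages)
    n_rogues: int = 0
    rogue_reuse_range: tuple = (50, 200)

    def __post_init__(self) -> None:
        for g, b in self.beta.items():
            if not 0 < b <= 1:
                raise ValueError(f"beta for group {g} must be in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class GroundTruth:
    group_of: dict
    kernel_ids: list
    group_specific_ids: dict
    shared_extra_ids: list
    fsf_ages: dict  # fsf id -> nd in [0, 1]
    group_trees: dict  # group -> Phylogeny (Yule, within-group)
    targets: pd.DataFrame  # taxon, group, target_reuse, target_use
    rogues: list


def yule_tree(labels: Sequence[str], rng: np.random.Generator,
              min_branch: float = 0.0) -> Phylogeny:
    """Pure-birth tree: uniform random topology with exponential depths.

    `min_branch` floors every branch; raising it guarantees signal on every
    edge of the generating tree (used by the high-signal presets).
    """
    labels = list(labels)
    if len(labels) == 1:
        return Phylogeny(Node(label=labels[0]), rooted=True)
    if len(labels) == 2:
        root = Node()
        a = root.add(Node(label=labels[0]))
        b = root.add(Node(label=labels[1]))
        a.length = b.length = min_branch + float(rng.exponential(1.0))
        tree = Phylogeny(root, rooted=True)
    else:
        tree = random_topology(labels, rng)
        tree.rooted = True
        for node in tree.postorder():
            if node.parent is not None:
                node.length = min_branch + float(rng.exponential(1.0))
    return tree


def _brownian_leaf_values(
    tree: Phylogeny, n_series: int, sigma: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Brownian walk of an n_series vector along the tree; leaf values."""
    values = {id(tree.root): np.zeros(n_series)}
    out = {}
    for node in tree.preorder():
        if node.parent is None:
            if node.is_leaf:  # single-taxon group
                out[node.label] = values[id(node)]
            continue
        t = node.length if node.length is not None else 1.0
        step = rng.normal(0.0, sigma * np.sqrt(max(t, 1e-9)), size=n_series)
        values[id(node)] = values[id(node.parent)] + step
        if node.is_leaf:
            out[node.label] = values[id(node)]
    return out


def generate_census(config: GeneratorConfig) -> tuple[CensusMatrix, GroundTruth]:
    """Draw a census matrix with planted group, age, and scaling structure."""
    rng = np.random.default_rng(config.seed)
    groups = [g for g in GROUP_ORDER if config.n_taxa.get(g, 0) > 0]

    kernel = [f"k.{i}.1" for i in range(config.kernel_size)]
    specific = {
        g: [f"{g.lower()}.{i}.1" for i in range(config.group_specific_n)] for g in groups
    }
    extras = [f"x.{i}.1" for i in range(config.shared_extra_n)]
    fsf_ids = kernel + [f for g in groups for f in specific[g]] + extras

    # ages: kernel ancient, group blocks ordered V < A < B < E, extras spread
    age_bands = {"V": (0.15, 0.30), "A": (0.30, 0.50), "B": (0.50, 0.70), "E": (0.70, 0.90)}
    ages = {f: float(rng.uniform(0.0, 0.08)) for f in kernel}
    for g in groups:
        lo, hi = age_bands[g]
        for f in specific[g]:
            ages[f] = float(rng.uniform(lo, hi))
    for f in extras:
        ages[f] = float(rng.uniform(0.10, 1.0))

    taxa, group_of, rows, target_rows = [], {}, [], []
    group_trees = {}

    for g in groups:
        n_g = config.n_taxa[g]
        labels = [f"{g}{i + 1:02d}" for i in range(n_g)]
        tree = yule_tree(labels, rng, config.min_branch)
        group_trees[g] = tree
        pool_ids = kernel + specific[g] + extras
        n_pool = len(pool_ids)
        bm = _brownian_leaf_values(tree, n_pool, config.bm_sigma, rng)

        # composition scores: kernel FSFs rank first (most ancient, most
        # frequently carried), then the group's own block, then the shared
        # extras.  A fixed per-group offset shifts which universal FSFs the
        # group prefers -- this is what lets parsimony recover monophyly
        # after group-specific characters are filtered out.
        # the group's own FSF block ranks alongside the upper kernel, so even
        # the group's smallest proteomes carry a good share of it
        base_rank = np.concatenate(
            [
                np.arange(len(kernel), dtype=float),
                np.arange(len(specific[g]), dtype=float) + 8.0,
                np.arange(len(extras), dtype=float) + len(kernel),
            ]
        )
        group_offset = rng.normal(0.0, config.profile_sigma, size=n_pool)
        group_score = base_rank + group_offset
        # each group also reuses the shared FSFs in its own proportions:
        # a fixed per-group lognormal profile over the pool, so taxa of the
        # same group agree on which universal FSFs are abundant vs rare
        logw_profile = rng.normal(0.0, config.profile_logw_sigma, size=n_pool)
        # composition preferences drift along the group's own tree, so close
        # relatives carry nested, similar FSF repertoires
        rank_bm = _brownian_leaf_values(tree, n_pool, config.rank_jitter, rng)

        lo, hi = config.reuse_range[g]
        logN = rng.uniform(np.log(lo), np.log(hi), size=n_g)
        if config.size_by_tree and n_g > 1:
            # hand out the drawn sizes in depth-first leaf order, so related
            # taxa have similar proteome sizes
            leaf_order = [n.label for n in tree.preorder() if n.is_leaf]
            rank_of = {lab: i for i, lab in enumerate(leaf_order)}
            sorted_logN = np.sort(logN)
            logN = np.array([sorted_logN[rank_of[lab]] for lab in labels])
        for t_idx, label in enumerate(labels):
            N = int(round(np.exp(logN[t_idx])))
            eps = rng.normal(0.0, config.sigma_v)
            V = int(round(config.heaps_c[g] * N ** config.beta[g] * np.exp(eps)))
            V = max(4, min(V, n_pool, N))
            # per-taxon jitter: most of the kernel is kept, some of it is
            # absent in any one taxon, so ancestral (zero) states remain
            # scattered across universal characters
            score = group_score + rank_bm[label]
            chosen = np.argsort(score)[:V]
            # Zipf-like weights by composition rank, modulated by the
            # phylogenetically autocorrelated Brownian factor
            w = (np.argsort(np.argsort(score[chosen])) + 1.0) ** (-config.zipf_gamma[g])
            w = w * np.exp(logw_profile[chosen] + bm[label][chosen])
            w /= w.sum()
            counts = np.ones(len(chosen), dtype=np.int64)
            if N > V:
                counts += rng.multinomial(N - V, w)
            row = np.zeros(len(fsf_ids), dtype=np.int64)
            global_idx = [fsf_ids.index(pool_ids[c]) for c in chosen]
            row[global_idx] = counts
            rows.append(row)
            taxa.append(label)
            group_of[label] = g
            target_rows.append((label, g, N, V))

    rogues = []
    for r in range(config.n_rogues):
        label = f"R{r + 1:02d}"
        g = groups[int(rng.integers(len(groups)))]
        lo, hi = config.rogue_reuse_range
        N = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        V = max(4, min(int(round(0.3 * N ** 0.8)), len(fsf_ids), N))
        chosen = rng.choice(len(fsf_ids), size=V, replace=False)
        w = rng.dirichlet(np.ones(V))
        counts = np.ones(V, dtype=np.int64)
        if N > V:
            counts += rng.multinomial(N - V, w)
        row = np.zeros(len(fsf_ids), dtype=np.int64)
        row[chosen] = counts
        rows.append(row)
        taxa.append(label)
        group_of[label] = g
        rogues.append(label)
        target_rows.append((label, g, N, V))

    census = CensusMatrix(
        taxa=taxa,
        groups=group_of,
        fsf_ids=fsf_ids,
        abundance=np.vstack(rows),
    )
    truth = GroundTruth(
        group_of=dict(group_of),
        kernel_ids=kernel,
        group_specific_ids=specific,
        shared_extra_ids=extras,
        fsf_ages=ages,
        group_trees=group_trees,
        targets=pd.DataFrame(
            target_rows, columns=["taxon", "group", "target_reuse", "target_use"]
        ),
        rogues=rogues,
    )
    return census, truth


@dataclass
class AccretionConfig:
    """Study conditions for the accretion-mode census.

    Unlike the composition sampler, every abundance is the endpoint of an
    explicit evolutionary walk on a single global tree whose backbone is
    (V, (A, (B, E))): the root carries only a modest ancient kernel, domain
    gains outnumber losses along every path, and per-clade growth factors
    reproduce the V < A < B < E proteome-size ladder.  This is the
    high-signal regime: characters are individually noisy but collectively
    consistent with one genealogy, so parsimony estimates are robust to
    taxon deletion and rooting falls on the kernel-only (viral) side.
    """

    seed: int
    n_taxa: dict = field(default_factory=lambda: {"V": 4, "A": 4, "B": 4, "E": 4})
    kernel_size: int = 60
    group_specific_n: int = 30
    shared_extra_n: int = 90
    ancestor_reuse: float = 2000.0
    kernel_zipf: float = 0.9  # rank-frequency slope of the ancestral kernel
    backbone_len: float = 2.0  # branch length of the inter-group backbone
    min_branch: float = 0.3
    bm_sigma: float = 0.2  # log-abundance Brownian noise per unit time
    growth: dict = field(default_factory=lambda: {"V": 0.5, "A": 2.0, "B": 3.2, "E": 4.2})
    #   per-clade log-growth of total abundance (accretion ladder)
    gain_rate: float = 0.06  # per unit time, per absent candidate FSF
    loss_rate: float = 0.015  # per unit time, per present non-kernel FSF
    gain_init: float = 0.35  # initial abundance of a gained FSF, as a
    #   fraction of the current per-FSF mean


def generate_accretion_census(config: AccretionConfig) -> tuple[CensusMatrix, GroundTruth]:
    """Evolve a census along one global tree with gains outpacing losses."""
    rng = np.random.default_rng(config.seed)
    groups = [g for g in GROUP_ORDER if config.n_taxa.get(g, 0) > 0]
    kernel = [f"k.{i}.1" for i in range(config.kernel_size)]
    specific = {g: [f"{g.lower()}.{i}.1" for i in range(config.group_specific_n)]
                for g in groups}
    extras = [f"x.{i}.1" for i in range(config.shared_extra_n)]
    fsf_ids = kernel + [f for g in groups for f in specific[g]] + extras
    idx = {f: i for i, f in enumerate(fsf_ids)}
    n_fsf = len(fsf_ids)

    # global tree: (V, (A, (B, E))) backbone with Yule subtrees
    group_trees = {g: yule_tree([f"{g}{i + 1:02d}" for i in range(config.n_taxa[g])],
                                rng, config.min_branch) for g in groups}

    def subtree_spec(g):
        def tup(node):
            return node.label if node.is_leaf else tuple(tup(c) for c in node.children)
        return tup(group_trees[g].root)

    nested = subtree_spec(groups[-1])
    for g in reversed(groups[1:-1]):
        nested = (subtree_spec(g), nested)
    global_tree = Phylogeny.from_topology((subtree_spec(groups[0]), nested),
                                          rooted=True)
    # backbone branches get the configured length; within-group branches
    # keep their Yule lengths (re-drawn here, preorder-deterministic)
    group_leaf = {lab: g for g in groups
                  for lab in group_trees[g].leaf_labels()}
    below: dict[int, set] = {}
    for node in global_tree.postorder():
        if node.is_leaf:
            below[id(node)] = {group_leaf[node.label]}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
    for node in global_tree.postorder():
        if node.parent is None:
            continue
        if len(below[id(node)]) > 1 or len(below[id(node.parent)]) > 1:
            node.length = config.backbone_len
        else:
            node.length = config.min_branch + float(rng.exponential(1.0))

    # ancestral state: kernel only, Zipf-ranked abundances scaled to the
    # ancestor's total reuse
    ranks = np.arange(1, len(kernel) + 1, dtype=float)
    w = ranks ** (-config.kernel_zipf)
    anc = np.zeros(n_fsf)
    anc[: len(kernel)] = np.log(np.maximum(config.ancestor_reuse * w / w.sum(), 1.0))

    depth_of = {id(global_tree.root): 0.0}
    max_depth = 0.0
    for node in global_tree.preorder():
        if node.parent is not None:
            depth_of[id(node)] = depth_of[id(node.parent)] + (node.length or 0.0)
            max_depth = max(max_depth, depth_of[id(node)])

    ages = {f: 0.0 for f in kernel}
    states = {id(global_tree.root): anc}
    rows_by_label = {}
    for node in global_tree.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        cur = states[id(node.parent)].copy()
        present = cur > 0
        # pure Brownian change within clades; the accretion jump of each
        # group is carried entirely by its entry branch, so within-group
        # data stay additive (no artifactual ancestor-descendant grades)
        is_entry = (len(below[id(node)]) == 1
                    and len(below[id(node.parent)]) > 1)
        drift = config.growth[next(iter(below[id(node)]))] if is_entry else 0.0
        cur[present] += rng.normal(drift, config.bm_sigma * np.sqrt(t),
                                   size=present.sum())
        # gains: group-specific block becomes available inside its clade;
        # shared extras are available everywhere
        available = np.zeros(n_fsf, dtype=bool)
        available[[idx[f] for f in extras]] = True
        if len(below[id(node)]) == 1:  # group blocks arise only inside their clade
            (g_here,) = below[id(node)]
            available[[idx[f] for f in specific[g_here]]] = True
        gainable = np.where(available & ~present)[0]
        p_gain = 1.0 - np.exp(-config.gain_rate * t)
        gained = gainable[rng.random(len(gainable)) < p_gain]
        if len(gained):
            mean_ln = cur[cur > 0].mean()
            cur[gained] = np.log(max(config.gain_init, 1e-3)) + mean_ln
            mid_depth = depth_of[id(node.parent)] + 0.5 * t
            for gi in gained:
                ages.setdefault(fsf_ids[gi], mid_depth / max_depth)
        # losses: rare, never the kernel
        losable = np.where(present)[0]
        losable = losable[losable >= len(kernel)]
        p_loss = 1.0 - np.exp(-config.loss_rate * t)
        lost = losable[rng.random(len(losable)) < p_loss]
        cur[lost] = 0.0
        states[id(node)] = cur
        if node.is_leaf:
            counts = np.zeros(n_fsf, dtype=np.int64)
            nz = cur > 0
            counts[nz] = np.maximum(1, np.round(np.exp(cur[nz])).astype(np.int64))
            rows_by_label[node.label] = counts

    for f in fsf_ids:
        ages.setdefault(f, 1.0)  # never gained anywhere

    taxa = [lab for g in groups for lab in group_trees[g].leaf_labels()]
    group_of = {lab: group_leaf[lab] for lab in taxa}
    abundance = np.vstack([rows_by_label[lab] for lab in taxa])
    census = CensusMatrix(taxa=taxa, groups=group_of, fsf_ids=fsf_ids,
                          abundance=abundance)
    table = pd.DataFrame({
        "taxon": taxa,
        "group": [group_of[t] for t in taxa],
        "target_reuse": abundance.sum(axis=1),
        "target_use": (abundance > 0).sum(axis=1),
    })
    truth = GroundTruth(
        group_of=dict(group_of),
        kernel_ids=kernel,
        group_specific_ids=specific,
        shared_extra_ids=extras,
        fsf_ages=ages,
        group_trees={**group_trees, "global": global_tree},
        targets=table,
        rogues=[],
    )
    return census, truth


def generate_tree_set(
    base_tree: Phylogeny,
    n_trees: int,
    nni_moves_per_tree: int = 0,
    rogue_leaves: Sequence[str] = (),
    seed: int = 0,
):
    """Perturbed replicates of a base topology (test bed for LS/TII/rogues).

    Each replicate applies `nni_moves_per_tree` random NNI moves, then
    detaches every rogue leaf and reattaches it on a uniformly random edge.
    """
    from phylotrace.stability import TreeSet
    from phylotrace.trees import nni_neighbors, _detach_subtree

    if nni_moves_per_tree < 0:
        raise ValueError("nni_moves_per_tree must be >= 0")
    rng = np.random.default_rng(seed)
    base = base_tree if not base_tree.rooted else base_tree.unroot()
    trees = []
    for _ in range(n_trees):
        tree = base.copy()
        for _ in range(nni_moves_per_tree):
            nbs = nni_neighbors(tree)
            tree = nbs[int(rng.integers(len(nbs)))]
        for rogue in rogue_leaves:
            tree = tree.prune_leaf(rogue)
            edges = tree.edges()
            attach_leaf(tree, edges[int(rng.integers(len(edges)))], rogue)
        trees.append(tree)
    return TreeSet(trees=trees, provenance={"n": n_trees, "seed": seed,
                                            "nni_moves": nni_moves_per_tree,
                                            "rogues": list(rogue_leaves)})


def ancestor_profile(
    census: CensusMatrix, fsf_ages: dict, nd_cutoff: float
) -> pd.Series:
    """Occurrence row for a reconstructed ancestor: FSFs no younger than the cutoff."""
    if not 0 <= nd_cutoff <= 1:
        raise ValueError("nd_cutoff must be in [0, 1]")
    missing = [f for f in census.fsf_ids if f not in fsf_ages]
    if missing:
        raise KeyError(f"FSFs without an age: {missing}")
    return pd.Series(
        {f: 1 if fsf_ages[f] <= nd_cutoff else 0 for f in census.fsf_ids},
        name="ancestor",
    )
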