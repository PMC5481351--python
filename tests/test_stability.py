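from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from helpers import dendropy_node_distances, quartet_type_by_splits
from phylotrace.census import encode
from phylotrace.stability import (
    TreeSet,
    bootstrap_trees,
    consensus,
    detect_rogues,
    explicitly_agree,
    leaf_stability,
    stability_report,
    taxon_instability,
)
from phylotrace.synth import generate_tree_set
from phylotrace.trees import Phylogeny, nni_neighbors, random_topology


@pytest.fixture
def base8():
    return random_topology([f"t{i}" for i in range(8)], np.random.default_rng(0))


@pytest.fixture
def identical_set(base8):
    return generate_tree_set(base8, 8, 0, seed=1)


class TestLeafStability:
    def test_identical_trees_all_variants_one(self, identical_set):
        for variant in ("max", "difference", "entropy"):
            ls = leaf_stability(identical_set, variant=variant)
            assert (ls == 1.0).all()

    def test_difference_never_exceeds_max(self, base8):
        ts = generate_tree_set(base8, 6, 2, seed=3)
        ls_max = leaf_stability(ts, "max")
        ls_diff = leaf_stability(ts, "difference")
        assert (ls_diff <= ls_max + 1e-12).all()

    def test_matches_exhaustive_quartet_oracle(self):
        # 5-leaf pair {T1, NNI(T1)}: brute-force the 5 quartets by hand
        rng = np.random.default_rng(2)
        t1 = random_topology(list("ABCDE"), rng)
        t2 = nni_neighbors(t1)[0]
        ts = TreeSet(trees=[t1, t2])
        for variant in ("max", "difference", "entropy"):
            got = leaf_stability(ts, variant=variant)
            labels = sorted(t1.leaf_labels())
            expected = {}
            for leaf in labels:
                scores = []
                for quartet in combinations(labels, 4):
                    if leaf not in quartet:
                        continue
                    counts = np.zeros(3)
                    for t in (t1, t2):
                        k = quartet_type_by_splits(t, *quartet)
                        if k >= 0:
                            counts[k] += 1
                    f = np.sort(counts / counts.sum())[::-1] if counts.sum() else None
                    if f is None:
                        scores.append(0.0)
                    elif variant == "max":
                        scores.append(f[0])
                    elif variant == "difference":
                        scores.append(f[0] - f[1])
                    else:
                        nz = f[f > 0]
                        scores.append(1.0 + (nz * np.log(nz)).sum() / np.log(3))
                expected[leaf] = np.mean(scores)
            for leaf in labels:
                assert got[leaf] == pytest.approx(expected[leaf])

    def test_quartet_cap_sampling_close_to_exhaustive(self, base8):
        ts = generate_tree_set(base8, 6, 1, seed=4)
        full = leaf_stability(ts, "max")
        capped = leaf_stability(ts, "max", quartet_cap=20, seed=0)
        assert (abs(full - capped) < 0.35).all()

    def test_too_few_leaves(self):
        tri = Phylogeny.from_topology(("A", ("B", "C")), rooted=False)
        with pytest.raises(ValueError):
            leaf_stability(TreeSet(trees=[tri, tri.copy()]), "max")


class TestExplicitlyAgree:
    def test_identical_binary_trees(self, base8):
        ea = explicitly_agree(base8, base8.copy())
        assert (ea == 1.0).all()

    def test_star_vs_binary_zero(self):
        binary = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
        star = Phylogeny.from_newick("(A,B,C,D);", rooted=False)
        assert (explicitly_agree(binary, star) == 0.0).all()

    def test_matches_quartet_oracle_on_nni_pair(self):
        rng = np.random.default_rng(5)
        t1 = random_topology(list("ABCDEF"), rng)
        t2 = nni_neighbors(t1)[1]
        got = explicitly_agree(t1, t2)
        labels = sorted(t1.leaf_labels())
        for leaf in labels:
            agree = total = 0
            for quartet in combinations(labels, 4):
                if leaf not in quartet:
                    continue
                total += 1
                k1 = quartet_type_by_splits(t1, *quartet)
                k2 = quartet_type_by_splits(t2, *quartet)
                agree += int(k1 >= 0 and k1 == k2)
            assert got[leaf] == pytest.approx(agree / total)

    def test_leaf_mismatch_rejected(self, base8):
        other = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
        with pytest.raises(ValueError):
            explicitly_agree(base8, other)


class TestTaxonInstability:
    def test_identical_trees_zero(self, identical_set):
        assert (taxon_instability(identical_set) == 0.0).all()

    def test_matches_direct_formula_via_dendropy(self):
        rng = np.random.default_rng(6)
        t1 = random_topology(list("ABCDEF"), rng)
        t2 = nni_neighbors(t1)[0]
        t3 = nni_neighbors(t1)[3]
        ts = TreeSet(trees=[t1, t2, t3])
        got = taxon_instability(ts)
        labels, mats = None, []
        for t in (t1, t2, t3):
            labels, d = dendropy_node_distances(t)
            mats.append(d)
        for i, leaf in enumerate(labels):
            expected = 0.0
            for x, y in combinations(range(3), 2):
                for j in range(len(labels)):
                    if j == i:
                        continue
                    dx, dy = mats[x][i, j], mats[y][i, j]
                    expected += abs(dx - dy) / (dx + dy) ** 2
            assert got[leaf] == pytest.approx(expected)

    def test_moved_caterpillar_leaf_has_maximal_tii(self):
        t1 = Phylogeny.from_topology(
            ("A", ("B", ("C", ("D", ("E", "F"))))), rooted=False
        )
        # X rides at one end, then at the other
        ta = Phylogeny.from_topology(
            (("X", "A"), ("B", ("C", ("D", ("E", "F"))))), rooted=False
        )
        tb = Phylogeny.from_topology(
            ("A", ("B", ("C", ("D", ("E", ("F", "X")))))), rooted=False
        )
        tii = taxon_instability(TreeSet(trees=[ta, tb]))
        assert tii.idxmax() == "X"

    def test_invariant_to_tree_order(self, base8):
        ts = generate_tree_set(base8, 5, 1, seed=7)
        fwd = taxon_instability(ts)
        rev = taxon_instability(TreeSet(trees=ts.trees[::-1]))
        pd.testing.assert_series_equal(fwd, rev)


class TestConsensusAndRogues:
    def test_single_tree_is_its_own_consensus(self, base8):
        cons = consensus(TreeSet(trees=[base8]), "strict")
        assert cons.topology_key() == base8.topology_key()

    def test_strict_consensus_collapses_exactly_the_nni_edge(self, base8):
        other = nni_neighbors(base8)[0]
        cons = consensus(TreeSet(trees=[base8, other]), "strict")
        assert cons.splits() == base8.splits() & other.splits()
        assert len(cons.splits()) == len(base8.splits()) - 1

    def test_majority_rule_keeps_two_of_three(self, base8):
        other = nni_neighbors(base8)[0]
        cons = consensus(TreeSet(trees=[base8, base8.copy(), other]), "majority")
        assert cons.topology_key() == base8.topology_key()

    def test_identical_trees_no_rogues(self, identical_set):
        assert detect_rogues(identical_set) == []

    def test_random_attachment_leaf_detected_first(self, base8):
        ts = generate_tree_set(base8, 12, 0, rogue_leaves=["t5"], seed=8)
        rogues = detect_rogues(ts, max_drop=2)
        assert rogues and rogues[0] == "t5"

    def test_report_bundles_all_metrics(self, base8):
        ts = generate_tree_set(base8, 5, 1, seed=9)
        report = stability_report(ts, groups={l: "A" for l in ts.labels})
        assert set(report.table.columns) >= {
            "group", "ls_max", "ls_difference", "ls_entropy", "tii", "rogue_rank"
        }
        assert report.table[["ls_max", "ls_difference", "ls_entropy"]].le(1).all().all()
        assert report.table["tii"].ge(0).all()


class TestBootstrap:
    def test_same_seed_same_trees(self, default_census):
        census, _ = default_census
        m = encode(census, 24)
        a = bootstrap_trees(m, n_reps=3, seed=5)
        b = bootstrap_trees(m, n_reps=3, seed=5)
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_clean_matrix_gives_identical_replicates(self):
        # many redundant copies of two perfectly compatible characters
        import numpy as np
        from phylotrace.census import CharacterMatrix

        states = np.tile(np.array([[0, 0], [0, 0], [9, 0], [9, 9], [9, 9]]), (1, 10))
        m = CharacterMatrix(
            taxa=list("ABCDE"),
            characters=[f"c{j}" for j in range(20)],
            states=states,
            n_states=24,
        )
        ts = bootstrap_trees(m, n_reps=5, seed=0)
        keys = {t.topology_key() for t in ts.trees}
        assert len(keys) == 1

    def test_planted_clade_support_high(self, accretion_census):
        census, _ = accretion_census
        m = encode(census, 24)
        ts = bootstrap_trees(m, n_reps=10, seed=1)
        allt = frozenset(m.taxa)
        anchor = min(allt)
        viral = frozenset(t for t in m.taxa if census.groups[t] == "V")
        canon = viral if anchor not in viral else allt - viral
        support = sum(canon in t.splits() for t in ts.trees) / len(ts)
        assert support >= 0.9
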