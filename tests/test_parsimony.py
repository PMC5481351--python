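import numpy as np
import pytest

from helpers import all_topologies, brute_force_wagner, group_monophyly
from phylotrace.census import CharacterMatrix, encode
from phylotrace import parsimony as pe
from phylotrace.trees import Phylogeny, random_topology


def random_matrix(rng, n_taxa, n_chars=5, max_state=4):
    return CharacterMatrix(
        taxa=[f"t{i}" for i in range(n_taxa)],
        characters=[f"c{j}" for j in range(n_chars)],
        states=rng.integers(0, max_state, size=(n_taxa, n_chars)),
        n_states=24,
    )


class TestWagnerLength:
    def test_identical_rows_zero_length(self):
        m = CharacterMatrix(
            taxa=list("ABCD"), characters=["c1", "c2"],
            states=np.tile([2, 5], (4, 1)), n_states=24,
        )
        for tree in all_topologies(list("ABCD")):
            assert pe.wagner_length(m, tree).length == 0

    def test_quartet_hand_values(self, quartet_matrix, quartet_trees):
        good, bad = quartet_trees
        assert pe.wagner_length(quartet_matrix, good).length == 3
        assert pe.wagner_length(quartet_matrix, bad).length == 6

    def test_matches_assignment_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(12):
            m = random_matrix(rng, int(rng.integers(4, 7)), n_chars=3)
            tree = random_topology(m.taxa, rng)
            assert pe.wagner_length(m, tree).length == brute_force_wagner(m, tree)

    def test_branch_lengths_sum_to_length(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 6)
        tree = random_topology(m.taxa, rng)
        score = pe.wagner_length(m, tree)
        assert sum(score.branch_lengths.values()) == score.length

    def test_length_bounds(self):
        # sum of ranges <= L <= star-tree length, for every topology
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, n_chars=4, max_state=6)
        ranges, star = pe.character_bounds(m)
        for tree in all_topologies(m.taxa):
            L = pe.tree_length(m, tree)
            assert ranges.sum() <= L <= star.sum()

    def test_leaf_mismatch_reports_difference(self, quartet_matrix):
        tree = Phylogeny.from_topology((("A", "B"), ("C", "X")), rooted=False)
        with pytest.raises(ValueError, match="X"):
            pe.wagner_length(quartet_matrix, tree)


class TestSearch:
    def test_finds_exhaustive_optimum(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            m = random_matrix(rng, int(rng.integers(4, 8)))
            lens = [pe.tree_length(m, t) for t in all_topologies(m.taxa)]
            _, score = pe.search(m, strategy="SPR", n_starts=3, seed=trial)
            assert score.length == min(lens)

    def test_recovers_strong_signal_topology(self):
        # clean additive characters generated on a known 6-taxon tree
        truth = Phylogeny.from_topology(
            ((("A", "B"), "C"), (("D", "E"), "F")), rooted=False
        )
        states = np.array([
            # A  B  C  D  E  F   per character
            [0, 0, 0, 9, 9, 9],
            [0, 0, 1, 9, 9, 8],
            [0, 1, 4, 9, 8, 5],
            [2, 2, 2, 7, 7, 7],
            [0, 0, 3, 9, 9, 6],
        ]).T
        m = CharacterMatrix(taxa=list("ABCDEF"), characters=[f"c{j}" for j in range(5)],
                            states=states, n_states=24)
        best, _ = pe.search(m, strategy="SPR", n_starts=3, seed=0)
        assert any(t.topology_key() == truth.topology_key() for t in best)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 7)
        a, sa = pe.search(m, strategy="SPR", n_starts=3, seed=42)
        b, sb = pe.search(m, strategy="SPR", n_starts=3, seed=42)
        assert sa.length == sb.length
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]

    def test_too_few_taxa(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            pe.search(random_matrix(rng, 3), seed=0)


class TestLundbergRooting:
    def test_quartet_roots_on_low_state_side(self, quartet_matrix, quartet_trees):
        good, _ = quartet_trees
        res = pe.lundberg_root(quartet_matrix, good)
        assert res.polarization == "min"
        assert res.attachment_costs["min"] == 0
        assert res.rooted_lengths["min"] == 3
        assert res.tree.unroot().topology_key() == good.topology_key()

    def test_unroot_round_trip_random(self):
        rng = np.random.default_rng(7)
        for trial in range(15):
            m = random_matrix(rng, int(rng.integers(4, 8)))
            tree = random_topology(m.taxa, rng)
            res = pe.lundberg_root(m, tree)
            assert res.tree.unroot().topology_key() == tree.topology_key()
            assert pe.tree_length(m, res.tree) == pe.tree_length(m, tree)

    def test_inverse_polarization_never_better(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m = random_matrix(rng, 6)
            tree = random_topology(m.taxa, rng)
            report = pe.inverse_polarization_check(m, tree)
            assert report["margin"] >= 0

    def test_mirrored_matrix_polarization_tie(self):
        # state columns and their mirror images over the full 0..S-1 range:
        # both polarizations cost the same by symmetry
        states = np.array([[0, 23], [8, 15], [15, 8], [23, 0]])
        m = CharacterMatrix(taxa=list("ABCD"), characters=["c", "cm"],
                            states=states, n_states=24)
        tree = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
        report = pe.inverse_polarization_check(m, tree)
        assert report["margin"] == 0
        res = pe.lundberg_root(m, tree)
        assert res.tie and res.polarization == "min"

    def test_accretion_data_min_polarization_wins(self, accretion_census):
        census, truth = accretion_census
        m = encode(census, 24)
        best, _ = pe.search(m, strategy="SPR", n_starts=2, seed=0)
        report = pe.inverse_polarization_check(m, best[0])
        assert report["optimal_polarization"] == "min"
        assert report["margin"] > 0

    def test_root_separates_kernel_group(self, accretion_census):
        # the root must fall on the branch splitting the ancient-kernel
        # (viral) group, whichever taxon happens to be smallest
        census, truth = accretion_census
        m = encode(census, 24)
        best, _ = pe.search(m, strategy="SPR", n_starts=2, seed=0)
        res = pe.lundberg_root(m, best[0])
        stack = [res.tree.root.children[0]]
        side = set()
        while stack:
            n = stack.pop()
            if n.is_leaf:
                side.add(n.label)
            stack.extend(n.children)
        groups = {census.groups[t] for t in side}
        other = {census.groups[t] for t in set(census.taxa) - side}
        assert groups == {"V"} or other == {"V"}


class TestDiagnostics:
    def test_retention_index_quartet(self, quartet_matrix, quartet_trees):
        good, bad = quartet_trees
        assert pe.retention_index(quartet_matrix, good) == pytest.approx(1.0)
        assert pe.retention_index(quartet_matrix, bad) == pytest.approx(0.0)

    def test_retention_index_none_when_undefined(self):
        m = CharacterMatrix(taxa=list("ABCD"), characters=["c"],
                            states=np.array([[0], [0], [0], [5]]), n_states=24)
        # single-taxon deviation: G == M, RI undefined
        tree = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
        assert pe.retention_index(m, tree) is None

    def test_retention_index_near_zero_for_shuffled_labels(self):
        rng = np.random.default_rng(9)
        truth = Phylogeny.from_topology(
            ((("A", "B"), ("C", "D")), (("E", "F"), ("G", "H"))), rooted=False
        )
        states = np.array([[0, 0, 0, 0, 9, 9, 9, 9]] * 6).T
        m = CharacterMatrix(taxa=list("ABCDEFGH"), characters=[f"c{j}" for j in range(6)],
                            states=states, n_states=24)
        assert pe.retention_index(m, truth) == pytest.approx(1.0)
        ris = []
        for _ in range(20):
            perm = rng.permutation(8)
            shuffled = CharacterMatrix(
                taxa=list("ABCDEFGH"), characters=m.characters,
                states=states[perm], n_states=24,
            )
            ris.append(pe.retention_index(shuffled, truth))
        assert np.mean(ris) < 0.5

    def test_farris_f_zero_for_identical_taxa(self):
        m = CharacterMatrix(taxa=list("ABCD"), characters=["c"],
                            states=np.zeros((4, 1), dtype=int), n_states=24)
        tree = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
        assert pe.farris_f(m, tree) == 0

    def test_farris_f_nonnegative_and_prefers_best_tree(
        self, quartet_matrix, quartet_trees
    ):
        good, bad = quartet_trees
        f_good = pe.farris_f(quartet_matrix, good)
        f_bad = pe.farris_f(quartet_matrix, bad)
        assert f_good == 0  # patristic == Manhattan on the generating split
        assert f_bad >= f_good

    def test_farris_f_nonnegative_random(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            m = random_matrix(rng, 6)
            tree = random_topology(m.taxa, rng)
            assert pe.farris_f(m, tree) >= 0

    def test_g1_none_for_degenerate_matrix(self):
        m = CharacterMatrix(taxa=[f"t{i}" for i in range(6)], characters=["c"],
                            states=np.ones((6, 1), dtype=int), n_states=24)
        assert pe.g1_statistic(m, n_random_trees=100, seed=0) is None

    def test_g1_negative_for_structured_matrix(self, accretion_census):
        census, _ = accretion_census
        m = encode(census, 24)
        g1 = pe.g1_statistic(m, n_random_trees=150, seed=0)
        assert g1 < 0

    def test_g1_requires_enough_trees(self, quartet_matrix):
        with pytest.raises(ValueError):
            pe.g1_statistic(quartet_matrix, n_random_trees=10, seed=0)


class TestGainsLosses:
    def test_two_leaf_gain(self):
        m = CharacterMatrix(taxa=["A", "B"], characters=["c"],
                            states=np.array([[0], [3]]), n_states=24)
        root = Phylogeny.from_topology(("A", "B"), rooted=True)
        tally = pe.tally_gains_losses(m, root)
        assert tally["gains"] == 3 and tally["losses"] == 0

    def test_totals_equal_rooted_length(self, quartet_matrix, quartet_trees):
        good, _ = quartet_trees
        res = pe.lundberg_root(quartet_matrix, good)
        tally = pe.tally_gains_losses(quartet_matrix, res.tree)
        assert tally["gains"] + tally["losses"] == pe.tree_length(
            quartet_matrix, res.tree
        )

    def test_unrooted_input_rejected(self, quartet_matrix, quartet_trees):
        good, _ = quartet_trees
        with pytest.raises(ValueError, match="rooted"):
            pe.tally_gains_losses(quartet_matrix, good)

    def test_accretion_data_gains_exceed_losses(self, accretion_census):
        census, _ = accretion_census
        m = encode(census, 24)
        best, _ = pe.search(m, strategy="SPR", n_starts=2, seed=0)
        res = pe.lundberg_root(m, best[0])
        tally = pe.tally_gains_losses(m, res.tree, polarization=res.polarization)
        assert tally["gains"] > tally["losses"]


def test_group_monophyly_on_default_census(default_census):
    census, _ = default_census
    m = encode(census, 24)
    best, _ = pe.search(m, strategy="SPR", n_starts=2, seed=11)
    mono = group_monophyly(best[0], census.groups)
    assert all(mono.values()), mono
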