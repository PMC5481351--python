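import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phylotrace.census import (
    CensusMatrix,
    encode,
    filter_universal,
    from_nexus,
    read_census,
    to_nexus,
    universal_fsf_ids,
    use_reuse,
    write_census,
)


def make_census(abundance, groups=None, taxa=None, fsf_ids=None):
    abundance = np.asarray(abundance)
    taxa = taxa or [f"t{i}" for i in range(abundance.shape[0])]
    fsf_ids = fsf_ids or [f"f{j}" for j in range(abundance.shape[1])]
    groups = groups or {t: "A" for t in taxa}
    return CensusMatrix(taxa=taxa, groups=groups, fsf_ids=fsf_ids, abundance=abundance)


class TestReadWrite:
    def test_direct_read_use_reuse(self, tmp_path, tiny_census):
        path = tmp_path / "census.tsv"
        write_census(tiny_census, path)
        census = read_census(path, {"t1": "A", "t2": "B"})
        table = use_reuse(census).set_index("taxon")
        assert table.loc["t1", "use"] == 1 and table.loc["t1", "reuse"] == 1
        assert table.loc["t2", "use"] == 2 and table.loc["t2", "reuse"] == 5

    def test_duplicate_fsf_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon\tf1\tf1\nt1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate FSF"):
            read_census(path, {"t1": "A"})

    def test_non_integer_cell_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon\tf1\tf2\nt1\t1\t2.5\n")
        with pytest.raises(ValueError, match="f2"):
            read_census(path, {"t1": "A"})

    def test_missing_group_label_rejected(self, tmp_path, tiny_census):
        path = tmp_path / "census.tsv"
        write_census(tiny_census, path)
        with pytest.raises(ValueError, match="t2"):
            read_census(path, {"t1": "A"})

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        census = make_census(rng.integers(0, 50, size=(20, 50)))
        path = tmp_path / "census.tsv"
        write_census(census, path)
        back = read_census(path, census.groups)
        assert back.taxa == census.taxa
        assert back.fsf_ids == census.fsf_ids
        np.testing.assert_array_equal(back.abundance, census.abundance)


class TestUniversalFiltering:
    def test_group_absent_fsf_dropped(self):
        # f0 present in A,B,E only; f1 universal
        census = make_census(
            [[1, 1], [1, 2], [1, 1], [0, 3]],
            groups={"t0": "A", "t1": "B", "t2": "E", "t3": "V"},
        )
        kept = universal_fsf_ids(census, "ABEV")
        assert kept == ["f1"]

    def test_all_zero_column_dropped_without_group_requirement(self):
        census = make_census([[1, 0], [2, 0]])
        assert universal_fsf_ids(census, []) == ["f0"]

    def test_planted_universal_bookkeeping(self):
        rng = np.random.default_rng(0)
        groups = {f"t{i}": "ABEV"[i % 4] for i in range(16)}
        universal = rng.integers(1, 9, size=(16, 30))  # present everywhere
        specific = np.zeros((16, 20), dtype=int)
        for i in range(16):  # each group-specific FSF only in one group
            for j in range(20):
                if j % 4 == i % 4:
                    specific[i, j] = 1 + int(rng.integers(5))
        census = make_census(np.hstack([universal, specific]), groups=groups)
        kept = universal_fsf_ids(census, "ABEV")
        assert kept == [f"f{j}" for j in range(30)]
        filtered = filter_universal(census, "ABEV")
        assert filtered.fsf_ids == kept and filtered.taxa == census.taxa

    def test_idempotent(self, default_census):
        census, _ = default_census
        once = filter_universal(census)
        twice = filter_universal(once)
        assert once.fsf_ids == twice.fsf_ids
        np.testing.assert_array_equal(once.abundance, twice.abundance)

    def test_empty_result_is_error(self):
        census = make_census([[1, 0], [0, 1]], groups={"t0": "A", "t1": "B"})
        with pytest.raises(ValueError, match="broaden"):
            filter_universal(census, "AB")

    def test_use_reuse_total_vs_universal_correlated(self):
        # mirrors the published strong use/reuse correlation, which is
        # computed on hundreds of proteomes; sampled at comparable depth
        from phylotrace.synth import GeneratorConfig, generate_census

        census, _ = generate_census(
            GeneratorConfig(seed=0, n_taxa={"V": 60, "A": 20, "B": 20, "E": 20})
        )
        total = use_reuse(census)
        uni = use_reuse(census, universal_fsf_ids(census))
        for col in ("use", "reuse"):
            rho = spearmanr(total[col], uni[col]).statistic
            assert rho > 0.9

    def test_unknown_subset_errors(self, tiny_census):
        with pytest.raises(KeyError):
            use_reuse(tiny_census, ["nope"])

    def test_empty_subset_gives_zeros(self, tiny_census):
        table = use_reuse(tiny_census, [])
        assert (table["use"] == 0).all() and (table["reuse"] == 0).all()


class TestEncoding:
    def test_endpoints(self):
        census = make_census([[0], [63]])
        m = encode(census, 24)
        assert m.states.ravel().tolist() == [0, 23]

    def test_log_scale_values(self):
        # round((S-1) * ln(a+1)/ln 64) for a in (0, 3, 7, 63)
        census = make_census([[0], [3], [7], [63]])
        m = encode(census, 24)
        assert m.states.ravel().tolist() == [0, 8, 12, 23]

    def test_constant_nonzero_column_uninformative(self):
        census = make_census([[5], [5], [5]])
        m = encode(census, 24)
        assert m.states.ravel().tolist() == [23, 23, 23]
        assert not m.parsimony_informative[0]

    @pytest.mark.parametrize("n_states", [24, 32, 64])
    def test_monotone_within_character(self, n_states):
        rng = np.random.default_rng(4)
        census = make_census(rng.integers(0, 1000, size=(12, 8)))
        m = encode(census, n_states)
        assert m.states.min() >= 0 and m.states.max() <= n_states - 1
        for j in range(8):
            a = census.abundance[:, j]
            s = m.states[:, j]
            order = np.argsort(a)
            assert (np.diff(s[order]) >= 0).all()

    def test_invariant_to_taxon_order(self):
        rng = np.random.default_rng(5)
        abundance = rng.integers(0, 100, size=(8, 5))
        census = make_census(abundance)
        perm = rng.permutation(8)
        shuffled = make_census(abundance[perm], taxa=[f"t{i}" for i in perm])
        m1, m2 = encode(census, 24), encode(shuffled, 24)
        np.testing.assert_array_equal(m1.states[perm], m2.states)

    def test_all_zero_characters_dropped(self):
        census = make_census([[1, 0], [4, 0]])
        m = encode(census, 24)
        assert m.characters == ["f0"]


class TestNexus:
    def test_symbols_24(self):
        census = make_census([[0], [1]])
        assert encode(census, 24).symbols == "0123456789ABCDEFGHIJKLMN"

    @pytest.mark.parametrize("shape", [(2, 1), (24, 40)])
    def test_round_trip(self, tmp_path, shape):
        rng = np.random.default_rng(6)
        census = make_census(rng.integers(0, 200, size=shape))
        m = encode(census, 24)
        path = tmp_path / "m.nex"
        to_nexus(m, path)
        back = from_nexus(path, 24)
        assert back.taxa == m.taxa
        np.testing.assert_array_equal(back.states, m.states)
        text = path.read_text()
        assert 'SYMBOLS="0123456789ABCDEFGHIJKLMN"' in text
        assert "ord: 1-" in text
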