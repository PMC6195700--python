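"""Table I/O, lineage parsing, and inclusion filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lotteryassembly import (
    AbundanceTable,
    FilterConfig,
    Lineage,
    TableParseError,
    build_groups,
    filter_features,
    filter_groups,
    filter_samples,
    read_biom_table,
    read_metaphlan_table,
    read_taxonomy_tsv,
    read_tsv_table,
    to_relative,
    write_tsv_table,
)
from lotteryassembly.tables import min_required_samples

from conftest import random_relative_table


class TestLineage:
    @pytest.mark.parametrize(
        "text,genus,depth",
        [
            ("k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; "
             "f__Veillonellaceae; g__Dialister", "Dialister", 6),
            # empty suffixes below class -> unannotated from class down
            ("k__Bacteria; p__Firmicutes; c__; o__; f__; g__", None, 2),
            ("", None, 0),
            ("k__Bacteria; p__Proteobacteria; c__unclassified; g__Serratia", None, 2),
        ],
    )
    def test_greengenes_parsing(self, text, genus, depth):
        lineage = Lineage.from_greengenes(text)
        assert lineage.get("genus") == genus
        assert lineage.depth == depth

    def test_prefix_closure_enforced(self):
        # a gap at family truncates genus too
        lineage = Lineage.from_greengenes("k__A; p__B; c__C; o__D; f__; g__G")
        assert lineage.get("genus") is None
        with pytest.raises(ValueError):
            Lineage((None, "Firmicutes", None, None, None, None, None))

    def test_clade_path_roundtrip_and_errors(self):
        lineage = Lineage.from_clade_path("k__A|p__B|c__C|o__D|f__E|g__F|s__G")
        assert lineage.get("species") == "G"
        with pytest.raises(TableParseError):
            Lineage.from_clade_path("p__B|k__A")  # ranks out of order


class TestTsvRoundTrip:
    def test_roundtrip_values_and_lineages(self, tmp_path, tiny_table, tiny_lineages):
        path = tmp_path / "table.tsv"
        counts = AbundanceTable(tiny_table.data * 1000, "counts")
        write_tsv_table(counts, tiny_lineages, path)
        table2, lineages2 = read_tsv_table(path)
        assert table2.feature_ids == counts.feature_ids
        assert table2.sample_ids == counts.sample_ids
        assert np.allclose(table2.data.to_numpy(), counts.data.to_numpy(), atol=1e-12)
        assert lineages2 == tiny_lineages

    def test_duplicate_feature_id_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("#OTU ID\ts1\notuA\t3\notuA\t4\n")
        with pytest.raises(TableParseError, match="otuA"):
            read_tsv_table(path)

    def test_empty_taxonomy_gives_unannotated(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#OTU ID\ts1\ttaxonomy\notuA\t3\t\n")
        _, lineages = read_tsv_table(path)
        assert lineages["otuA"] == Lineage.unannotated()


class TestBiom:
    def test_biom_hdf5_roundtrip(self, tmp_path):
        h5py = pytest.importorskip("h5py")
        from scipy import sparse

        mat = sparse.csr_matrix(np.array([[5.0, 0.0], [1.0, 2.0], [0.0, 7.0]]))
        tax = [b"k__Bacteria; p__P; c__C; o__O; f__F; g__A",
               b"k__Bacteria; p__P; c__C; o__O; f__F; g__B",
               b""]
        path = tmp_path / "t.biom"
        with h5py.File(path, "w") as f:
            f.create_dataset("observation/ids", data=[b"o1", b"o2", b"o3"])
            f.create_dataset("sample/ids", data=[b"s1", b"s2"])
            f.create_dataset("observation/matrix/data", data=mat.data)
            f.create_dataset("observation/matrix/indices", data=mat.indices)
            f.create_dataset("observation/matrix/indptr", data=mat.indptr)
            f.create_dataset("observation/metadata/taxonomy", data=tax)
        table, lineages = read_biom_table(path)
        assert table.kind == "counts"
        assert table.data.loc["o2", "s2"] == 2.0
        assert lineages["o1"].get("genus") == "A"
        assert lineages["o3"] == Lineage.unannotated()

    def test_malformed_hdf5_names_problem(self, tmp_path):
        h5py = pytest.importorskip("h5py")
        path = tmp_path / "bad.biom"
        with h5py.File(path, "w") as f:
            f.create_dataset("not_biom", data=[1])
        with pytest.raises(TableParseError):
            read_biom_table(path)


class TestMetaphlan:
    def _write(self, tmp_path, rows):
        path = tmp_path / "mpa.tsv"
        path.write_text("clade_name\tS1\tS2\n" + "\n".join(rows) + "\n")
        return path

    def test_percent_conversion_and_species_retention(self, tmp_path):
        path = self._write(tmp_path, [
            "k__A|p__B|c__C|o__D|f__E|g__F\t99.0\t80.0",          # genus summary row
            "k__A|p__B|c__C|o__D|f__E|g__F|s__X\t12.5\t80.0",
            "k__A|p__B|c__C|o__D|f__E|g__F|s__Y\t86.5\t0.0",
        ])
        table, lineages = read_metaphlan_table(path)
        assert table.kind == "relative"
        # only maximal-depth rows kept as base features
        assert sorted(table.feature_ids) == ["s__X", "s__Y"]
        assert table.data.loc["s__X", "S1"] == pytest.approx(0.125)
        assert lineages["s__X"].get("species") == "X"

    def test_zero_species_rows_is_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("clade_name\tS1\n")
        with pytest.raises(TableParseError, match="no data rows"):
            read_metaphlan_table(path)

    def test_negative_abundance_is_error(self, tmp_path):
        path = self._write(tmp_path, ["k__A|p__B|c__C|o__D|f__E|g__F|s__X\t-1\t0"])
        with pytest.raises(TableParseError, match="negative"):
            read_metaphlan_table(path)


class TestFilterSamples:
    def test_strictly_less_removal(self):
        data = pd.DataFrame([[4999, 5000, 8000]], index=["o1"],
                            columns=["a", "b", "c"], dtype=float)
        out = filter_samples(AbundanceTable(data, "counts"))
        assert out.sample_ids == ["b", "c"]

    def test_identity_when_all_pass(self):
        data = pd.DataFrame([[6000, 7000]], index=["o1"], columns=["a", "b"], dtype=float)
        out = filter_samples(AbundanceTable(data, "counts"))
        assert out.sample_ids == ["a", "b"]
        out1 = filter_samples(AbundanceTable(data, "counts"),
                              FilterConfig(min_reads_per_sample=1))
        assert out1.sample_ids == ["a", "b"]

    def test_zero_survivors_is_error(self):
        data = pd.DataFrame([[10.0]], index=["o1"], columns=["a"])
        with pytest.raises(ValueError):
            filter_samples(AbundanceTable(data, "counts"))


class TestToRelative:
    def test_column_normalization(self):
        data = pd.DataFrame({"a": [10.0, 30.0], "b": [5.0, 0.0]}, index=["o1", "o2"])
        out = to_relative(AbundanceTable(data, "counts"))
        assert out.kind == "relative"
        assert out.data["a"].tolist() == [0.25, 0.75]
        assert out.data["b"].tolist() == [1.0, 0.0]

    def test_kind_mismatch_and_zero_column(self):
        rel = AbundanceTable(pd.DataFrame({"a": [1.0]}, index=["o1"]), "relative")
        with pytest.raises(ValueError):
            to_relative(rel)
        zero = AbundanceTable(pd.DataFrame({"a": [0.0]}, index=["o1"]), "counts")
        with pytest.raises(ValueError):
            filter_samples(zero, FilterConfig(min_reads_per_sample=1))


def _uniform_feature_table(qualifying: int, n_samples: int, value: float = 0.001):
    """One feature above threshold in `qualifying` samples, tiny elsewhere."""
    row = np.full(n_samples, 1e-6)
    row[:qualifying] = value
    other = 1.0 - row
    data = pd.DataFrame([row, other], index=["rare", "common"],
                        columns=[f"s{i}" for i in range(n_samples)])
    return AbundanceTable(data, "relative")


class TestFilterFeatures:
    @pytest.mark.parametrize(
        "n_samples,qualifying,kept",
        [
            (2000, 9, False),    # floor of 10 dominates ceil(0.005*2000)=10
            (2000, 10, True),
            (10000, 49, False),  # ceil(0.005*10000) = 50
            (10000, 50, True),
        ],
    )
    def test_min_sample_rule(self, n_samples, qualifying, kept):
        table = _uniform_feature_table(qualifying, n_samples)
        out = filter_features(table)
        assert ("rare" in out.feature_ids) is kept

    def test_strict_abundance_inequality(self):
        # exactly at the floor everywhere -> never qualifies
        n = 100
        data = pd.DataFrame([np.full(n, 0.0005), np.full(n, 0.9995)],
                            index=["at_floor", "big"],
                            columns=[f"s{i}" for i in range(n)])
        out = filter_features(AbundanceTable(data, "relative"))
        assert out.feature_ids == ["big"]

    def test_no_renormalization_after_removal(self):
        table = _uniform_feature_table(3, 100)
        out = filter_features(table)
        kept = out.data.loc["common"]
        assert np.array_equal(kept.to_numpy(), table.data.loc["common"].to_numpy())

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        table = random_relative_table(rng, 12, 60)
        once = filter_features(table)
        twice = filter_features(once)
        assert once.feature_ids == twice.feature_ids

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        table = random_relative_table(rng, 8, 30)
        cfg = FilterConfig(otu_min_abundance=0.02, otu_min_samples_floor=3,
                           otu_min_sample_fraction=0.05)
        out = filter_features(table, cfg)
        need = max(3, math.ceil(0.05 * 30))
        for fid in table.feature_ids:
            count = sum(1 for s in table.sample_ids if table.data.loc[fid, s] > 0.02)
            assert (fid in out.feature_ids) == (count >= need)


class TestBuildGroups:
    def test_partition_of_annotated_features(self, tiny_lineages):
        groups = build_groups(tiny_lineages, "genus")
        assert [(g.group_name, g.n_members) for g in groups] == [("A", 2), ("B", 1)]
        members = [m for g in groups for m in g.members]
        assert sorted(members) == sorted(tiny_lineages)  # union = annotated set
        assert len(set(members)) == len(members)         # pairwise disjoint

    def test_unannotated_features_in_no_group(self, tiny_lineages):
        lineages = dict(tiny_lineages)
        lineages["otu4"] = Lineage.from_greengenes("k__Bacteria; p__P; c__; o__; f__; g__")
        groups = build_groups(lineages, "genus")
        assert all("otu4" not in g.members for g in groups)

    def test_all_unannotated_gives_empty_list(self):
        lineages = {"o1": Lineage.unannotated()}
        assert build_groups(lineages, "genus") == []


class TestFilterGroups:
    def _table_with_group_abundance(self, qualifying: int, n_samples: int):
        row = np.full(n_samples, 1e-4)
        row[:qualifying] = 0.02
        data = pd.DataFrame([row / 2, row / 2, 1.0 - row],
                            index=["a1", "a2", "b1"],
                            columns=[f"s{i}" for i in range(n_samples)])
        table = AbundanceTable(data, "relative")
        from lotteryassembly import GroupAssignment

        return table, [GroupAssignment("genus", "A", ("a1", "a2")),
                       GroupAssignment("genus", "B", ("b1",))]

    def test_floor_rule(self):
        table, groups = self._table_with_group_abundance(9, 1000)
        kept = filter_groups(table, groups)
        assert [g.group_name for g in kept] == ["B"]
        table, groups = self._table_with_group_abundance(10, 1000)
        kept = filter_groups(table, groups)
        assert [g.group_name for g in kept] == ["A", "B"]

    def test_override_is_strict(self):
        table, groups = self._table_with_group_abundance(200, 1000)
        cfg = FilterConfig(group_min_samples_override=200)
        kept = filter_groups(table, groups, cfg)
        assert all(g.group_name != "A" for g in kept)  # exactly 200 fails ">"
        table, groups = self._table_with_group_abundance(201, 1000)
        kept = filter_groups(table, groups, cfg)
        assert any(g.group_name == "A" for g in kept)

    def test_whole_table_group_retained(self):
        rng = np.random.default_rng(0)
        table = random_relative_table(rng, 5, 50)
        from lotteryassembly import GroupAssignment

        grp = GroupAssignment("genus", "ALL", tuple(table.feature_ids))
        assert filter_groups(table, [grp]) == [grp]

    def test_idempotent(self):
        table, groups = self._table_with_group_abundance(30, 100)
        once = filter_groups(table, groups)
        assert filter_groups(table, once) == once


def test_min_required_samples_ceil_semantics():
    assert min_required_samples(2000, 0.005, 10) == 10
    assert min_required_samples(10000, 0.005, 10) == 50
    assert min_required_samples(201, 0.005, 1) == 2  # ceil never rounds down


def test_taxonomy_tsv_reader(tmp_path):
    path = tmp_path / "tax.tsv"
    path.write_text("#feature_id\ttaxonomy\no1\tk__B; p__P; c__C; o__O; f__F; g__G\n")
    lineages = read_taxonomy_tsv(path)
    assert lineages["o1"].get("genus") == "G"
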