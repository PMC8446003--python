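"""OTU table I/O, relativization and pre-network filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conet import (
    Taxonomy,
    filter_gram_positive,
    filter_min_reads,
    read_otu_table,
    relativize,
    split_by_group,
    write_otu_table,
)

from conftest import make_table


def _write_fixture(tmp_path, counts_rows, taxonomy_rows, metadata_rows):
    c = tmp_path / "counts.tsv"
    c.write_text("\n".join("\t".join(r) for r in counts_rows) + "\n")
    t = tmp_path / "taxonomy.tsv"
    t.write_text("\n".join("\t".join(r) for r in taxonomy_rows) + "\n")
    m = tmp_path / "metadata.tsv"
    m.write_text("\n".join("\t".join(r) for r in metadata_rows) + "\n")
    return c, t, m


BASE_COUNTS = [
    ["sample_id", "OTU1", "OTU2", "Bd01", "OTU3"],
    ["s1", "5", "0", "2", "9"],
    ["s2", "1", "3", "0", "4"],
    ["s3", "2", "2", "1", "7"],
]
BASE_TAX = [
    ["OTU1", "Bacteria;Proteobacteria;Gamma;Pseudomonadales;Fam;Gen"],
    ["OTU2", "Bacteria;Firmicutes;Bacilli;Bacillales;Fam;Gen"],
    ["Bd01", "Bacteria;Proteobacteria;Delta;Bdellovibrionales;Fam;Gen"],
    ["OTU3", "Bacteria;Bacteroidetes;Cyto;Order;Fam;Gen"],
]
BASE_META = [
    ["sample_id", "site", "fraction", "date", "temperature"],
    ["s1", "SH", "floc", "2013-03-15", "18.0"],
    ["s2", "SH", "floc", "2013-04-15", "20.5"],
    ["s3", "SH", "floc", "2013-05-15", "23.0"],
]


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        paths = _write_fixture(tmp_path, BASE_COUNTS, BASE_TAX, BASE_META)
        table, tax = read_otu_table(*paths)
        assert table.mode == "raw_counts"
        assert table.guild.at["Bd01"] == "predator_bd"
        assert table.guild.at["OTU1"] == "prey_candidate"
        out_c, out_m = tmp_path / "out_c.tsv", tmp_path / "out_m.tsv"
        write_otu_table(table, out_c, out_m, taxonomy=tax, taxonomy_path=tmp_path / "out_t.tsv")
        table2, tax2 = read_otu_table(out_c, tmp_path / "out_t.tsv", out_m)
        assert table == table2
        assert tax.lineages == tax2.lineages

    def test_duplicate_sample_id_is_named_in_error(self, tmp_path):
        rows = BASE_COUNTS + [["s2", "1", "1", "1", "1"]]
        paths = _write_fixture(tmp_path, rows, BASE_TAX, BASE_META)
        with pytest.raises(ValueError, match="s2"):
            read_otu_table(*paths)

    def test_missing_temperature_is_allowed(self, tmp_path):
        meta = [r[:] for r in BASE_META]
        meta[2][4] = ""
        paths = _write_fixture(tmp_path, BASE_COUNTS, BASE_TAX, meta)
        table, _ = read_otu_table(*paths)
        assert np.isnan(table.sample_meta.at["s2", "temperature"])
        assert table.sample_meta.at["s1", "temperature"] == 18.0

    def test_sample_missing_from_metadata_errors(self, tmp_path):
        meta = BASE_META[:3]  # drops s3
        paths = _write_fixture(tmp_path, BASE_COUNTS, BASE_TAX, meta)
        with pytest.raises(ValueError, match="s3"):
            read_otu_table(*paths)

    def test_non_numeric_count_reports_coordinates(self, tmp_path):
        rows = [r[:] for r in BASE_COUNTS]
        rows[2][2] = "oops"
        paths = _write_fixture(tmp_path, rows, BASE_TAX, BASE_META)
        with pytest.raises(ValueError, match="s2.*OTU2|OTU2.*s2"):
            read_otu_table(*paths)


class TestRelativize:
    def test_forced_by_definition(self):
        t = make_table({"A": [2.0], "B": [3.0], "C": [5.0]})
        rel = relativize(t)
        assert np.allclose(rel.counts.iloc[0], [0.2, 0.3, 0.5])
        assert rel.mode == "relative"

    def test_rows_sum_to_one(self, small_table):
        rel = relativize(small_table)
        assert np.allclose(rel.counts.sum(axis=1), 1.0)

    def test_zero_total_sample_errors(self):
        t = make_table({"A": [1.0, 0.0], "B": [2.0, 0.0]})
        with pytest.raises(ValueError, match="s2"):
            relativize(t)

    def test_preserves_within_sample_rank_order(self, small_table):
        rel = relativize(small_table)
        for s in small_table.sample_ids:
            raw_order = np.argsort(small_table.counts.loc[s].to_numpy())
            rel_order = np.argsort(rel.counts.loc[s].to_numpy())
            assert (raw_order == rel_order).all()


class TestFilterMinReads:
    def test_strict_boundary(self):
        t = make_table({"At10": [5.0, 5.0], "At11": [5.0, 6.0]})
        out = filter_min_reads(t, threshold=10)
        assert out.otu_ids == ["At11"]

    def test_empty_table_stays_empty(self):
        t = make_table({"A": [1.0, 2.0]})
        empty = t.subset_otus([])
        out = filter_min_reads(empty)
        assert out.otu_ids == []
        assert out.sample_ids == t.sample_ids

    def test_rejects_relative_mode(self, small_table):
        with pytest.raises(ValueError, match="read counts"):
            filter_min_reads(relativize(small_table))

    def test_idempotent(self, small_table):
        once = filter_min_reads(small_table, threshold=50)
        twice = filter_min_reads(once, threshold=50)
        assert once.otu_ids == twice.otu_ids

    def test_per_sample_mode(self):
        t = make_table({"A": [11.0, 11.0], "B": [100.0, 3.0]})
        assert filter_min_reads(t, per_sample=True).otu_ids == ["A"]


class TestFilterGramPositive:
    def test_firmicutes_and_actinobacteria_prey_removed(self, small_table, toy_taxonomy):
        out = filter_gram_positive(small_table, toy_taxonomy)
        assert "PreyGP" not in out.otu_ids
        assert "PreyAct" not in out.otu_ids
        assert "PreyGN" in out.otu_ids

    def test_predators_never_removed(self, small_table, toy_taxonomy):
        out = filter_gram_positive(small_table, toy_taxonomy)
        assert "Bd001" in out.otu_ids and "Bx001" in out.otu_ids

    def test_unresolved_phylum_retained(self, small_table, toy_taxonomy):
        out = filter_gram_positive(small_table, toy_taxonomy)
        assert "PreyUnk" in out.otu_ids

    def test_commutes_with_min_reads_filter(self, small_table, toy_taxonomy):
        a = filter_gram_positive(filter_min_reads(small_table, 50), toy_taxonomy)
        b = filter_min_reads(filter_gram_positive(small_table, toy_taxonomy), 50)
        assert a.otu_ids == b.otu_ids


class TestSplitByGroup:
    @pytest.fixture
    def multi_site(self):
        return make_table(
            {"A": [1.0] * 6, "B": [2.0] * 6},
            sites=["SH", "SH", "AB", "AB", "LB", "LB"],
            fractions=["floc", "liquor"] * 3,
            dates=["2013-05-01", "2013-03-01", "2013-04-01", "2013-06-01",
                   "2013-07-01", "2013-08-01"],
        )

    def test_three_sites_two_fractions_gives_six_groups(self, multi_site):
        groups = split_by_group(multi_site, ["site", "fraction"])
        assert len(groups) == 6
        union = sorted(s for g in groups.values() for s in g.sample_ids)
        assert union == sorted(multi_site.sample_ids)

    def test_single_site_split_is_identity(self):
        t = make_table({"A": [1.0, 2.0]})
        groups = split_by_group(t, ["site"])
        assert list(groups) == [("SH",)]
        assert groups[("SH",)].sample_ids == t.sample_ids

    def test_groups_are_time_ordered(self, multi_site):
        groups = split_by_group(multi_site, ["site"])
        for g in groups.values():
            dates = g.sample_meta.loc[g.sample_ids, "date"]
            assert list(dates) == sorted(dates)

    def test_invalid_key_rejected(self, multi_site):
        with pytest.raises(ValueError, match="temperature"):
            split_by_group(multi_site, ["temperature"])


class TestTaxonomy:
    def test_lineage_padding_and_ranks(self):
        tax = Taxonomy.from_strings({"O1": "Bacteria;Proteobacteria"})
        assert tax.phylum("O1") == "Proteobacteria"
        assert tax.rank("O1", "order") == "unclassified"

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            Taxonomy(lineages={"O1": ()})

    def test_guild_from_order(self, toy_taxonomy):
        assert toy_taxonomy.guild_of("Bd001") == "predator_bd"
        assert toy_taxonomy.guild_of("Bx001") == "predator_bx"
        assert toy_taxonomy.guild_of("PreyGN") == "prey_candidate"


@given(
    st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=8),
    st.integers(min_value=0, max_value=50),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_min_reads_filter_idempotence_property(col, threshold):
    t = make_table({"A": [float(v) for v in col], "B": [1.0] * len(col)})
    once = filter_min_reads(t, threshold=threshold)
    twice = filter_min_reads(once, threshold=threshold)
    assert once.otu_ids == twice.otu_ids
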