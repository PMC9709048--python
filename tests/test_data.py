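import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mixedstock as ms
from mixedstock.datasets import nest_counts

HIST_PCT = {"CEFL": 1.36, "SOFL": 0.83, "MXQR": 1.05, "MXCA": 0.64, "MXTV": 0.53,
            "TORT": 87.30, "SWCB": 0.16, "SURN": 6.61, "AVES": 1.51}
RECENT_PCT = {"CEFL": 5.00, "SOFL": 3.23, "MXQR": 5.88, "MXCA": 5.57, "MXTV": 5.29,
              "TORT": 63.72, "SWCB": 0.12, "SURN": 9.70, "AVES": 1.48}


class TestLoadCountTable:
    def test_roundtrip_preserves_order_and_counts(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("site,Hb,Ha,Hc\nS2,1,1,1\nS1,1,1,1\n")
        t = ms.load_count_table(path, ms.SiteKind.ROOKERY)
        assert t.site_labels == ("S2", "S1")
        assert t.haplotype_labels == ("Hb", "Ha", "Hc")
        assert list(t.row_sums()) == [3, 3]
        out = tmp_path / "o.csv"
        ms.write_count_table(t, out)
        t2 = ms.load_count_table(out, ms.SiteKind.ROOKERY)
        assert t2.site_labels == t.site_labels
        assert t2.haplotype_labels == t.haplotype_labels
        assert np.array_equal(t2.counts, t.counts)

    def test_blank_cell_is_zero(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("site,A,B\nS1,,3\n")
        t = ms.load_count_table(path, ms.SiteKind.MIXED_STOCK)
        assert t.counts[0, 0] == 0 and t.row_sums()[0] == 3

    @pytest.mark.parametrize("cell", ["-2", "0.5", "abc"])
    def test_bad_cell_names_location(self, tmp_path, cell):
        path = tmp_path / "c.csv"
        path.write_text(f"site,A,B\nS1,{cell},3\n")
        with pytest.raises(ms.ValidationError, match="S1.*A|A.*S1"):
            ms.load_count_table(path, ms.SiteKind.ROOKERY)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ms.ValidationError, match="duplicate"):
            ms.HaplotypeCountTable(("S", "S"), ("A",), np.array([[1], [1]]), ms.SiteKind.ROOKERY)


class TestOrphanFilter:
    def test_orphan_column_dropped_and_reported(self, small_rookeries):
        mixed = ms.HaplotypeCountTable(
            ("MS1",), ("A", "B", "CM-X"), np.array([[5, 2, 3]]), ms.SiteKind.MIXED_STOCK
        )
        filtered, report = ms.filter_orphan_haplotypes(mixed, small_rookeries)
        assert filtered.haplotype_labels == ("A", "B")
        assert report.removed_counts == {"CM-X": 3}
        assert report.per_site == {"MS1": {"CM-X": 3}}

    def test_no_orphans_is_identity(self, small_rookeries, small_mixed):
        filtered, report = ms.filter_orphan_haplotypes(small_mixed, small_rookeries)
        assert filtered is small_mixed
        assert report.empty

    def test_idempotent(self, small_rookeries):
        mixed = ms.HaplotypeCountTable(
            ("MS1",), ("A", "CM-X"), np.array([[5, 3]]), ms.SiteKind.MIXED_STOCK
        )
        once, _ = ms.filter_orphan_haplotypes(mixed, small_rookeries)
        twice, rep = ms.filter_orphan_haplotypes(once, small_rookeries)
        assert np.array_equal(once.counts, twice.counts)
        assert rep.empty

    def test_all_orphan_site_errors(self, small_rookeries):
        mixed = ms.HaplotypeCountTable(
            ("BAD",), ("CM-X",), np.array([[4]]), ms.SiteKind.MIXED_STOCK
        )
        with pytest.raises(ms.ValidationError, match="BAD"):
            ms.filter_orphan_haplotypes(mixed, small_rookeries)


class TestRelativeSizes:
    @pytest.mark.parametrize("period,expected", [("historical", HIST_PCT), ("recent", RECENT_PCT)])
    def test_packaged_nest_counts_match_printed_percentages(self, period, expected):
        table = nest_counts(period)
        got = dict(zip(table.rookery_labels, table.percentages()))
        assert got == pytest.approx(expected, abs=5e-3)

    def test_single_rookery_is_one(self):
        t = ms.SourceSizeTable(("X",), np.array([123.0]), "p")
        assert ms.relative_sizes(t) == pytest.approx([1.0])

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_proportions_sum_to_one(self, sizes):
        t = ms.SourceSizeTable(tuple(f"r{i}" for i in range(len(sizes))), np.array(sizes), "p")
        assert ms.relative_sizes(t).sum() == pytest.approx(1.0)

    def test_rejects_nonpositive_sizes(self):
        with pytest.raises(ms.ValidationError):
            ms.SourceSizeTable(("a", "b"), np.array([1.0, 0.0]), "p")
        with pytest.raises(ms.ValidationError):
            ms.SourceSizeTable((), np.array([]), "p")


class TestSizeVariation:
    def test_period_change_matches_printed_values(self):
        hist = nest_counts("historical").proportions()
        rec = nest_counts("recent").proportions()
        labels = nest_counts("historical").rookery_labels
        var = dict(zip(labels, np.round(ms.size_variation(hist, rec), 2)))
        assert var["TORT"] == pytest.approx(-23.58)
        assert var["MXQR"] == pytest.approx(4.83)

    def test_identical_vectors_give_zero(self):
        p = np.array([0.3, 0.7])
        assert np.all(ms.size_variation(p, p) == 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ms.ValidationError, match="length"):
            ms.size_variation(np.array([0.5, 0.5]), np.array([1.0]))


class TestDatasetAssembly:
    def test_assemble_aligns_and_orders(self, small_rookeries, small_mixed):
        sizes = ms.SourceSizeTable(("R2", "R1"), np.array([300.0, 100.0]), "p")
        dist = ms.EffectiveDistanceMatrix(("MS1",), ("R2", "R1"), np.array([[2000.0, 1000.0]]))
        ds = ms.MSADataset.assemble(small_rookeries, small_mixed, sizes, dist)
        assert ds.sizes.rookery_labels == ("R1", "R2")
        assert list(ds.sizes.sizes) == [100.0, 300.0]
        assert np.array_equal(ds.distances.D, [[1000.0, 2000.0]])
        assert ds.haplotype_universe == ("A", "B")

    def test_label_mismatch_errors(self, small_rookeries, small_mixed):
        sizes = ms.SourceSizeTable(("R1", "OTHER"), np.array([1.0, 2.0]), "p")
        dist = ms.EffectiveDistanceMatrix(("MS1",), ("R1", "R2"), np.array([[1.0, 2.0]]))
        with pytest.raises(ms.ValidationError, match="OTHER|R2"):
            ms.MSADataset.assemble(small_rookeries, small_mixed, sizes, dist)
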