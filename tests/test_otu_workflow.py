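import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import distinct_assignments, metadata_for, table_from_counts
from otukit import otu_workflow as wf
from otukit.io_formats import TaxonomyString, make_seq_record


class TestSplitMerge:
    @pytest.mark.parametrize(
        "n, chunk_size, sizes",
        [
            (45000, 20000, [20000, 20000, 5000]),
            (10, 20000, [10]),
            (3, 1, [1, 1, 1]),
            (0, 20000, []),
        ],
    )
    def test_chunk_sizes(self, n, chunk_size, sizes):
        chunks = wf.split_sequences(range(n), chunk_size=chunk_size)
        assert [len(c) for c in chunks] == sizes
        assert [x for c in chunks for x in c] == list(range(n))

    def test_chunk_size_must_be_positive(self):
        with pytest.raises(ValueError):
            wf.split_sequences([1, 2], chunk_size=0)

    def test_merge_hand_checked_union(self):
        merged = wf.merge_otu_results([{"A": ["s1"]}, {"A": ["s2"], "B": ["s3"]}])
        assert merged == {"A": ["s1", "s2"], "B": ["s3"]}

    def test_merge_single_map_is_identity(self):
        m = {"A": ["s1", "s2"], "B": ["s3"]}
        assert wf.merge_otu_results([m]) == m

    def test_merge_rejects_duplicated_sequence_id(self):
        with pytest.raises(ValueError, match="s1"):
            wf.merge_otu_results([{"A": ["s1"]}, {"B": ["s1"]}])

    @pytest.mark.parametrize("chunk_size", [1, 7, 20000])
    def test_split_pick_merge_equals_direct_pick(self, chunk_size):
        """Distributing picking over chunks must be lossless for any chunking."""

        def mock_pick(records):
            # deterministic per-record picker: OTU from a content hash
            out = {}
            for r in records:
                out.setdefault(f"otu{hash(r) % 7}", []).append(r)
            return out

        records = [f"S{i % 5}_{i:05d}" for i in range(500)]
        direct = mock_pick(records)
        chunked = wf.merge_otu_results(
            [mock_pick(c) for c in wf.split_sequences(records, chunk_size)]
        )
        assert {k: sorted(v) for k, v in chunked.items()} == {
            k: sorted(v) for k, v in direct.items()
        }


class TestPrimerAverage:
    def test_shared_otu_scaled_to_mean(self):
        a = {"x": [f"a{i}" for i in range(10)]}
        b = {"x": [f"b{i}" for i in range(20)]}
        assert len(wf.primer_average(a, b)["x"]) == 15

    def test_exclusive_otus_pass_through(self):
        a = {"y": [f"a{i}" for i in range(7)]}
        b = {"z": ["b0"]}
        out = wf.primer_average(a, b)
        assert out["y"] == a["y"] and out["z"] == b["z"]

    def test_shared_singletons_survive_with_a_member(self):
        out = wf.primer_average({"z": ["a1"]}, {"z": ["b1"]})
        assert out["z"] == ["a1"]  # ceil(2/2) = 1, a-first

    def test_self_average_preserves_per_otu_counts(self):
        m = {"x": [f"a{i}" for i in range(9)], "y": ["a9"]}
        m2 = {k: [s + "'" for s in v] for k, v in m.items()}
        out = wf.primer_average(m, m2)
        assert {k: len(v) for k, v in out.items()} == {k: len(v) for k, v in m.items()}

    @given(
        na=st.integers(0, 30),
        nb=st.integers(0, 30),
        n_excl=st.integers(0, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_count_bounded_by_input(self, na, nb, n_excl):
        a = {}
        b = {}
        if na:
            a["shared"] = [f"a{i}" for i in range(na)]
        if nb:
            b["shared"] = [f"b{i}" for i in range(nb)]
        for i in range(n_excl):
            a[f"ax{i}"] = [f"ae{i}"]
            b[f"bx{i}"] = [f"be{i}"]
        out = wf.primer_average(a, b)
        total_in = sum(len(v) for v in a.values()) + sum(len(v) for v in b.values())
        total_out = sum(len(v) for v in out.values())
        assert total_out <= total_in
        shared = na > 0 and nb > 0
        assert (total_out == total_in) == (not shared)


class TestAssignTaxonomy:
    def test_direct_lookup(self):
        ref = {"42": TaxonomyString.parse("k__Bacteria; g__Escherichia; s__coli")}
        assign = wf.assign_taxonomy({"42": ["s1_1"]}, ref)
        assert assign.lineage("42") is ref["42"]
        assert not assign.missing

    def test_absent_id_gets_unassigned_sentinel(self):
        assign = wf.assign_taxonomy({"999": ["s1_1"]}, {})
        assert assign.lineage_str("999") == "Unassigned"
        assert assign.missing == {"999"}

    def test_missing_count_is_set_difference(self):
        rng = np.random.default_rng(2)
        ids = [str(i) for i in rng.permutation(1000)]
        ref = {i: TaxonomyString.parse(f"k__B; g__G{i}") for i in ids[:900]}
        assign = wf.assign_taxonomy({i: [f"S1_{i}"] for i in ids}, ref)
        assert len(assign.missing) == 100
        assert assign.missing == set(ids) - set(ref)


class TestCondense:
    def test_redundant_lineage_collapses_conserving_sequences(self):
        tax = TaxonomyString.parse("k__B; g__Escherichia; s__coli")
        assign = wf.TaxonomyAssignment(
            entries={o: (tax, o) for o in ("12", "7", "30")}
        )
        omap = {"12": ["a", "b"], "7": ["c", "d", "e"], "30": ["f", "g", "h", "i", "j"]}
        res = wf.condense_otus(assign, omap)
        assert list(res.otu_map) == ["12"]  # lexicographic min of {12, 7, 30}
        assert sorted(res.otu_map["12"]) == sorted("abcdefghij")
        assert res.representatives == {str(tax): "12"}

    def test_distinct_lineages_identity(self):
        omap = {"a": ["x1"], "b": ["x2"]}
        res = wf.condense_otus(distinct_assignments(["a", "b"]), omap)
        assert res.otu_map == omap

    def test_hundred_otus_seven_lineages(self):
        otus = [f"{i:03d}" for i in range(100)]
        entries = {
            o: (TaxonomyString.parse(f"k__B; g__G{i % 7}"), o)
            for i, o in enumerate(otus)
        }
        omap = {o: [f"S1_{o}"] for o in otus}
        res = wf.condense_otus(wf.TaxonomyAssignment(entries=entries), omap)
        assert len(res.otu_map) == 7
        all_in = sorted(s for v in omap.values() for s in v)
        all_out = sorted(s for v in res.otu_map.values() for s in v)
        assert all_in == all_out

    def test_unassigned_otu_rejected(self):
        with pytest.raises(ValueError, match="q"):
            wf.condense_otus(wf.TaxonomyAssignment(entries={}), {"q": ["s"]})


class TestPickRepresentatives:
    def test_sequence_copied_verbatim(self):
        ref = {"42": make_seq_record("42", "ACGTACGT")}
        recs = wf.pick_representatives(["42"], ref)
        assert len(recs) == 1 and str(recs[0].seq) == "ACGTACGT"

    def test_empty_id_list(self):
        assert wf.pick_representatives([], {}) == []

    def test_missing_id_named_in_error(self):
        ref = {str(i): make_seq_record(str(i), "AC") for i in range(9)}
        with pytest.raises(ValueError, match="'9'"):
            wf.pick_representatives([str(i) for i in range(10)], ref)


class TestFilterTransient:
    def _prevalence_table(self, n_present, filler_total=1000):
        """One focal aggregate in n_present of 100 samples, plus dense filler."""
        samples = [f"s{i}" for i in range(100)]
        focal = [50.0 if i < n_present else 0.0 for i in range(100)]
        filler = [float(filler_total)] * 100
        return table_from_counts({"focal": focal, "ubiq": filler}, samples)

    def test_prevalence_below_threshold_removed(self):
        table = self._prevalence_table(4)
        filtered, report = wf.filter_transient(
            table, distinct_assignments(["focal", "ubiq"])
        )
        assert "focal" not in filtered.otu_ids
        assert report.removed[0].pass_label == "prevalence"

    def test_prevalence_at_threshold_retained(self):
        table = self._prevalence_table(5)
        filtered, _ = wf.filter_transient(
            table, distinct_assignments(["focal", "ubiq"])
        )
        assert "focal" in filtered.otu_ids

    def test_abundance_boundary_strict(self):
        # grand total 100,000; threshold count = 10
        samples = [f"s{i}" for i in range(100)]
        low = [1.0 if i < 9 else 0.0 for i in range(100)]       # 9 seqs = 0.009%
        edge = [1.0 if i < 10 else 0.0 for i in range(100)]     # 10 seqs = 0.010%
        filler = [(100000.0 - 19.0) / 100] * 100
        table = table_from_counts(
            {"low": low, "edge": edge, "ubiq": filler}, samples
        )
        filtered, report = wf.filter_transient(
            table, distinct_assignments(["low", "edge", "ubiq"])
        )
        assert "low" not in filtered.otu_ids
        assert "edge" in filtered.otu_ids
        labels = {r.aggregate_id.split("g__")[-1].split(";")[0]: r.pass_label
                  for r in report.removed}
        assert all(v == "abundance" for v in labels.values())

    def test_zero_thresholds_are_identity(self, small_table, small_assignments):
        filtered, report = wf.filter_transient(
            small_table, small_assignments, prevalence_frac=0.0, abundance_frac=0.0
        )
        assert filtered.otu_ids == small_table.otu_ids
        assert not report.removed

    def test_conservation_of_grand_total(self, small_table, small_assignments):
        filtered, report = wf.filter_transient(
            small_table, small_assignments, prevalence_frac=0.5, abundance_frac=0.01
        )
        removed_total = sum(
            r.percent_abundance / 100 * small_table.grand_total()
            for r in report.removed
        )
        assert filtered.grand_total() + removed_total == pytest.approx(
            small_table.grand_total()
        )

    @given(
        prev=st.floats(0, 0.5),
        abund=st.floats(0, 0.01),
        bump_prev=st.floats(0, 0.5),
        bump_abund=st.floats(0, 0.01),
    )
    @settings(max_examples=25, deadline=None)
    def test_raising_thresholds_never_rescues_an_aggregate(
        self, prev, abund, bump_prev, bump_abund
    ):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(20)]
        counts = {
            f"o{i}": (rng.integers(0, 4, size=20) * rng.integers(0, 2, size=20)).astype(float)
            for i in range(15)
        }
        counts = {k: v for k, v in counts.items() if v.sum() > 0}
        table = table_from_counts({k: list(v) for k, v in counts.items()}, samples)
        assign = distinct_assignments(list(counts))
        lo, _ = wf.filter_transient(table, assign, prev, abund)
        hi, _ = wf.filter_transient(
            table, assign, min(prev + bump_prev, 1), min(abund + bump_abund, 1)
        )
        assert set(hi.otu_ids) <= set(lo.otu_ids)

    def test_report_includes_sequence_ids_with_map(self):
        samples = ["s0", "s1"]
        table = table_from_counts({"rare": [1.0, 0.0], "ubiq": [50.0, 50.0]}, samples)
        omap = {"rare": ["s0_1"], "ubiq": [f"s{i % 2}_{i + 2}" for i in range(100)]}
        _, report = wf.filter_transient(
            table, distinct_assignments(["rare", "ubiq"]),
            prevalence_frac=0.6, otu_map=omap,
        )
        assert report.removed[0].seq_ids == ["s0_1"]


class TestBuildOtuTable:
    def test_hand_counted_example(self):
        md = metadata_for(["S1", "S2"])
        table = wf.build_otu_table(
            {"otuA": ["S1_1", "S1_2", "S2_1"]},
            distinct_assignments(["otuA"]),
            md,
        )
        assert table.counts.loc["otuA", "S1"] == 2
        assert table.counts.loc["otuA", "S2"] == 1

    def test_empty_map_gives_zero_row_table(self):
        md = metadata_for(["S1", "S2"])
        table = wf.build_otu_table({}, wf.TaxonomyAssignment(entries={}), md)
        assert table.shape == (0, 2)

    def test_grand_total_conservation_random(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(20)]
        omap: dict[str, list[str]] = {}
        for i in range(10000):
            otu = f"otu{rng.integers(50)}"
            omap.setdefault(otu, []).append(f"S{rng.integers(20)}_{i:06d}")
        table = wf.build_otu_table(
            omap, distinct_assignments(list(omap)), metadata_for(samples)
        )
        assert table.grand_total() == 10000

    def test_unknown_sample_listed(self):
        md = metadata_for(["S1"])
        with pytest.raises(ValueError, match="S9_1"):
            wf.build_otu_table(
                {"otuA": ["S9_1"]}, distinct_assignments(["otuA"]), md
            )

    def test_sample_ids_may_contain_underscores(self):
        md = metadata_for(["My_Sample"])
        table = wf.build_otu_table(
            {"o": ["My_Sample_000001"]}, distinct_assignments(["o"]), md
        )
        assert table.counts.loc["o", "My_Sample"] == 1


def test_condense_then_table_conserves_column_sums(
    small_community, small_assignments, small_table
):
    res = wf.condense_otus(small_assignments, small_community.otu_map)
    condensed_table = wf.build_otu_table(
        res.otu_map, res.assignments, small_community.metadata
    )
    assert np.allclose(
        condensed_table.counts.values.sum(axis=0),
        small_table.counts.values.sum(axis=0),
    )
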