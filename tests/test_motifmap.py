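import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prolamap.motifmap import (
    MotifHit,
    MotifPanel,
    find_hits,
    load_panel,
    map_database,
    motif_metrics,
    summarize_by_group,
    write_panel,
)
from prolamap.seqio import SequenceRecord
from prolamap.synthetic import oracle_metrics


class TestPanel:
    def test_duplicates_collapsed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate motif"):
            panel = MotifPanel(["PFPQ", "PFPQ", "QQQQ"])
        assert panel.motifs == ["PFPQ", "QQQQ"]

    def test_nested_fragments_allowed(self):
        panel = MotifPanel(["QQPFPQ", "PFPQ"])  # one is a fragment of the other
        assert len(panel) == 2

    def test_non_standard_residue_rejected(self):
        with pytest.raises(ValueError):
            MotifPanel(["PFXQ"])

    def test_load_roundtrip(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("# coeliac toxic motifs\nPFPQ\nQQPFPQ  # nested\n\nQQQQ\n")
        panel = load_panel(p)
        assert panel.motifs == ["PFPQ", "QQPFPQ", "QQQQ"]
        out = tmp_path / "out.txt"
        write_panel(panel, out)
        assert load_panel(out).motifs == panel.motifs


class TestFindHits:
    def test_worked_example(self, worked_sequence, worked_panel):
        hits = find_hits(worked_sequence, worked_panel)
        assert [(h.motif, h.start, h.end) for h in hits] == [
            ("QQPFPQ", 1, 6),
            ("PFPQ", 3, 6),
            ("QQPFPQ", 9, 14),
            ("PFPQ", 11, 14),
        ]

    def test_empty_panel(self, worked_sequence):
        assert find_hits(worked_sequence, MotifPanel([], name="empty")) == []

    def test_motif_equal_to_sequence(self):
        seq = "QPQLPY"
        hits = find_hits(seq, MotifPanel([seq]))
        assert hits == [MotifHit(seq, 1, len(seq))]

    def test_overlapping_self_occurrences(self):
        hits = find_hits("QQQQQ", MotifPanel(["QQQQ"]))
        assert [(h.start, h.end) for h in hits] == [(1, 4), (2, 5)]


class TestMetrics:
    def test_worked_example(self, worked_sequence, worked_panel):
        mm = motif_metrics(worked_sequence, worked_panel)
        assert mm.unique_count == 2
        assert mm.density == pytest.approx(2 / 14)
        assert mm.coverage_percent == 85.71  # union [1,6] u [9,14]; 7-8 uncovered

    def test_no_match(self):
        mm = motif_metrics("AAAA", MotifPanel(["PFPQ"]))
        assert (mm.unique_count, mm.density, mm.coverage_percent) == (0, 0.0, 0.0)

    def test_full_cover(self):
        seq = "QPQLPYQP"
        mm = motif_metrics(seq, MotifPanel([seq]))
        assert mm.unique_count == 1
        assert mm.density == pytest.approx(1 / len(seq))
        assert mm.coverage_percent == 100.0

    @settings(max_examples=300, deadline=None)
    @given(st.data())
    def test_oracle_equivalence(self, data):
        seq = data.draw(st.text(alphabet="QPFLA", min_size=1, max_size=80))
        panel = MotifPanel(
            data.draw(
                st.lists(
                    st.text(alphabet="QPFLA", min_size=1, max_size=8),
                    min_size=0, max_size=8, unique=True,
                )
            )
        )
        ours = motif_metrics(seq, panel)
        ref = oracle_metrics(seq, panel)
        assert (ours.unique_count, ours.coverage_percent) == (ref.unique_count, ref.coverage_percent)
        assert ours.density == pytest.approx(ref.density)

    def test_monotone_in_panel(self, worked_sequence):
        base = MotifPanel(["PFPQ"])
        bigger = MotifPanel(["PFPQ", "QQPFPQ"])
        a = motif_metrics(worked_sequence, base)
        b = motif_metrics(worked_sequence, bigger)
        assert b.unique_count >= a.unique_count
        assert b.density >= a.density
        assert b.coverage_percent >= a.coverage_percent

    def test_bounds(self, toy_dataset):
        for rec in toy_dataset.clean_records:
            mm = motif_metrics(rec.sequence, toy_dataset.panel)
            assert mm.unique_count <= len(toy_dataset.panel)
            assert 0.0 <= mm.coverage_percent <= 100.0

    def test_sequence_doubling(self):
        # repeat-free construction: doubling S tiles hits identically, so
        # coverage is unchanged while density halves (m unchanged)
        seq = "AGKTVNDERH"
        panel = MotifPanel(["GKTV"])
        one = motif_metrics(seq, panel)
        two = motif_metrics(seq + seq, panel)
        assert two.coverage_percent == one.coverage_percent
        assert two.unique_count == one.unique_count
        assert two.density == pytest.approx(one.density / 2)


class TestMapDatabase:
    def test_matches_ground_truth(self, toy_dataset):
        clean = toy_dataset.clean_records
        metrics, _hits = map_database(clean, toy_dataset.panel)
        truth = {t.accession: t for t in toy_dataset.truth}
        for row in metrics.itertuples():
            t = truth[row.accession]
            assert row.m == t.m
            assert row.density == pytest.approx(t.density)
            assert row.coverage_pct == t.coverage_pct

    def test_empty_records(self, toy_dataset):
        metrics, hits = map_database([], toy_dataset.panel)
        assert metrics.empty and hits.empty

    def test_deterministic(self, toy_dataset):
        a = map_database(toy_dataset.clean_records, toy_dataset.panel)
        b = map_database(toy_dataset.clean_records, toy_dataset.panel)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestSummaries:
    def _metrics(self, values):
        return pd.DataFrame(
            {
                "accession": [f"r{i}" for i in range(len(values))],
                "L": [100] * len(values),
                "m": values,
                "density": [v / 100 for v in values],
                "density_per100": values,
                "coverage_pct": values,
            }
        )

    def test_group_of_one(self):
        df = self._metrics([7])
        out = summarize_by_group(df, {"r0": "g"})
        row = out[(out.group == "g") & (out.statistic == "m")].iloc[0]
        assert row["min"] == row.q1 == row["median"] == row.q3 == row["max"] == row["mean"] == 7

    def test_linear_interpolation_quartiles(self):
        df = self._metrics([0, 1, 2, 3, 4])
        out = summarize_by_group(df, {f"r{i}": "g" for i in range(5)})
        row = out[(out.group == "g") & (out.statistic == "m")].iloc[0]
        assert (row.q1, row["median"], row.q3) == (1.0, 2.0, 3.0)

    def test_unknown_accession_errors(self):
        df = self._metrics([1, 2])
        with pytest.raises(ValueError):
            summarize_by_group(df, {"r0": "g"})

    def test_group_sizes_conserve_rows(self, toy_dataset):
        metrics, _ = map_database(toy_dataset.clean_records, toy_dataset.panel)
        out = summarize_by_group(metrics, toy_dataset.groups_of())
        per_group_n = out[out.statistic == "m"].set_index("group")["n"]
        assert per_group_n.sum() == len(metrics)
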