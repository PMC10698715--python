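"""Isoform calling: labels, consistency rules, frequency estimation."""

import dataclasses

import pytest

from targetiso import (SimulationConfig, call_isoform, call_isoforms,
                       cumulative_segment_frequency, estimate_frequencies,
                       screen_read, screen_reads, simulate_reads)
from targetiso.calling import novel_label
from targetiso.errors import GeneModelError, ParameterError
from targetiso.screen import PresenceVector, SegmentHit


def _vector(model, segment_ids, read_id="r", full_length=True):
    hits = {s.segment_id: SegmentHit(s.segment_id in segment_ids,
                                     0 if s.segment_id in segment_ids else None,
                                     None)
            for s in model.segments}
    return PresenceVector(read_id, hits, full_length)


class TestCallIsoform:
    def test_zero_error_round_trip_label(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"K": 1.0}, n_reads=3,
                               sub_rate=0, ins_rate=0, del_rate=0, seed=2)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        for r in reads:
            call = call_isoform(screen_read(r, mouse_model), mouse_model)
            assert call.label == "K" and call.consistent

    def test_novel_signature_stable_label(self, mouse_model):
        # isoform F plus the never-observed predicted exon 5: a consistent
        # combination guaranteed to be absent from the catalog
        f_sig = mouse_model.catalog_by_label()["F"].segments
        plus5 = tuple(sorted(f_sig + ("5",),
                             key=mouse_model.segment_order.__getitem__))
        assert plus5 not in {iso.segments for iso in mouse_model.catalog}
        call1 = call_isoform(_vector(mouse_model, plus5), mouse_model)
        call2 = call_isoform(_vector(mouse_model, plus5, read_id="other"), mouse_model)
        assert call1.consistent
        assert call1.label.startswith("NOVEL:")
        assert call1.label == call2.label == novel_label(plus5)

    def test_terminal_rule_violation_is_inconsistent(self, mouse_model):
        # a stop-bearing terminal extension (8b) with material downstream (22)
        bad = ("2", "6", "7", "8a", "8b", "22")
        call = call_isoform(_vector(mouse_model, bad), mouse_model)
        assert not call.consistent

    def test_b_without_a_is_inconsistent(self, mouse_model):
        sig = ("2", "6", "7", "8b")
        call = call_isoform(_vector(mouse_model, sig), mouse_model)
        assert not call.consistent

    def test_foreign_vector_rejected(self, mouse_model, human_model):
        vec = _vector(human_model, ("2", "4"))
        with pytest.raises(GeneModelError):
            call_isoform(vec, mouse_model)


class TestEstimateFrequencies:
    def test_single_isoform_is_100_percent(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"A": 1.0}, n_reads=100,
                               sub_rate=0, ins_rate=0, del_rate=0, seed=3)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        table = estimate_frequencies(call_isoforms(vectors, mouse_model), vectors)
        assert table.denominator == 100
        assert table.frequency("A") == pytest.approx(100.0)

    def test_70_30_mixture_recovery(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 0.7, "K": 0.3},
                               n_reads=2000, seed=5)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        table = estimate_frequencies(call_isoforms(vectors, mouse_model), vectors)
        assert table.frequency("F") == pytest.approx(70.0, abs=3.0)
        assert table.frequency("K") == pytest.approx(30.0, abs=3.0)

    def test_non_full_length_reads_do_not_change_frequencies(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 0.5, "A": 0.5}, n_reads=200,
                               sub_rate=0, ins_rate=0, del_rate=0,
                               revcomp_frac=0, seed=7)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        table = estimate_frequencies(call_isoforms(vectors, mouse_model), vectors)
        # append polyA-less (non-full-length) copies: frequencies unchanged
        extra = [dataclasses.replace(r, read_id=r.read_id + "_nopA",
                                     sequence=r.sequence[:-20], quality=None)
                 for r in reads[:50]]
        vectors2 = screen_reads(list(reads) + extra, mouse_model)
        table2 = estimate_frequencies(call_isoforms(vectors2, mouse_model), vectors2)
        assert table2.denominator == table.denominator
        assert table2.frequency("F") == table.frequency("F")
        assert table2.frequency("A") == table.frequency("A")

    def test_zero_eligible_reads(self, mouse_model):
        table = estimate_frequencies([], [])
        assert table.denominator == 0
        assert len(table.table) == 0

    def test_frequencies_sum_to_100(self, mouse_model, barcodes):
        weights = {iso.label: iso.freq_label for iso in mouse_model.catalog}
        cfg = SimulationConfig(isoform_weights=weights, n_reads=500, seed=11)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        table = estimate_frequencies(call_isoforms(vectors, mouse_model), vectors)
        assert table.table["frequency_pct"].sum() == pytest.approx(100.0)

    def test_read_order_invariance(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 0.6, "G": 0.4}, n_reads=120,
                               seed=13)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        calls = call_isoforms(vectors, mouse_model)
        fwd = estimate_frequencies(calls, vectors)
        rev = estimate_frequencies(calls[::-1], vectors[::-1])
        assert fwd.denominator == rev.denominator
        assert fwd.frequency("F") == rev.frequency("F")


class TestCumulativeSegmentFrequency:
    def test_single_isoform_own_segment(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 1.0}, n_reads=30,
                               sub_rate=0, ins_rate=0, del_rate=0, seed=17)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        vectors = screen_reads(reads, mouse_model)
        table = estimate_frequencies(call_isoforms(vectors, mouse_model), vectors)
        assert cumulative_segment_frequency(table, "22", mouse_model) == pytest.approx(100.0)
        assert cumulative_segment_frequency(table, "18", mouse_model) == 0.0

    def test_unknown_segment_rejected(self, mouse_model):
        table = estimate_frequencies([], [])
        with pytest.raises(ParameterError):
            cumulative_segment_frequency(table, "99x", mouse_model)
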