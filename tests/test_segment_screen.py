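"""Segment detection: edit-distance semantics, full-length filter, discovery."""

import dataclasses
import math

import numpy as np
import pytest

from targetiso import (SimulationConfig, detect_ko_construct, detect_segment,
                       discovery_screen, is_full_length, screen_read,
                       simulate_reads)
from targetiso.model import Exon, IsoformDef
from targetiso.screen import has_polya
from targetiso.simulate import egfp_marker, reverse_complement

from conftest import random_dna
from oracles import infix_edit_distance, infix_edit_distance_both_strands


class TestDetectSegment:
    def test_verbatim_segment_present_at_zero(self, mouse_model):
        rng = np.random.default_rng(0)
        seg = mouse_model.segment_map["12"]
        read = random_dna(rng, 300) + seg.sequence + random_dna(rng, 300)
        hit = detect_segment(read, seg)
        assert hit.present and hit.best_distance == 0
        assert hit.position == 300

    def test_floor_boundary_at_40_percent(self):
        # 10-nt segment: floor(0.4*10) = 4 allowed errors.  Candidate reads are
        # validated against the DP oracle so the global minimum is exactly the
        # planted distance.
        rng = np.random.default_rng(7)
        found4 = found5 = False
        while not (found4 and found5):
            pattern = random_dna(rng, 10)
            for n_subs in (4, 5):
                mutated = list(pattern)
                for p in rng.choice(10, size=n_subs, replace=False):
                    mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
                read = random_dna(rng, 3) + "".join(mutated) + random_dna(rng, 3)
                d = infix_edit_distance_both_strands(pattern, read)
                if d != n_subs:
                    continue
                hit = detect_segment(read, pattern)
                assert hit.best_distance == d
                if n_subs == 4:
                    assert hit.present
                    found4 = True
                else:
                    assert not hit.present
                    found5 = True

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(11)
        for i in range(1000):
            plen = int(rng.integers(5, 31))
            tlen = int(rng.integers(plen, 201))
            pattern = random_dna(rng, plen)
            text = random_dna(rng, tlen)
            if i % 3 == 0:  # plant a mutated copy to exercise near matches
                copy = list(pattern)
                for p in rng.choice(plen, size=int(rng.integers(0, max(1, plen // 3))),
                                    replace=False):
                    copy[p] = "ACGT"[int(rng.integers(4))]
                off = int(rng.integers(0, tlen - plen + 1))
                text = text[:off] + "".join(copy) + text[off + plen:]
                text = text[:tlen]
            want = infix_edit_distance_both_strands(pattern, text)
            hit = detect_segment(text, pattern)
            assert hit.best_distance == want
            assert hit.present == (want <= math.floor(0.4 * plen))

    def test_strand_symmetry(self, mouse_model):
        rng = np.random.default_rng(13)
        seg = mouse_model.segment_map["14"]
        for _ in range(25):
            read = random_dna(rng, 200) + seg.sequence + random_dna(rng, 200)
            fwd = detect_segment(read, seg)
            rev = detect_segment(reverse_complement(read), seg)
            assert fwd.present == rev.present
            assert fwd.best_distance == rev.best_distance

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            pattern = random_dna(rng, 20)
            read = random_dna(rng, 150)
            prev = False
            for frac in (0.1, 0.2, 0.3, 0.4, 0.6, 0.9):
                present = detect_segment(read, pattern, max_mismatch_frac=frac).present
                assert present or not prev  # once present, stays present
                prev = prev or present

    def test_empty_read_absent(self, mouse_model):
        hit = detect_segment("", mouse_model.segment_map["12"])
        assert not hit.present and hit.best_distance is None


class TestFullLength:
    def test_zero_error_reads_pass(self, mouse_catalog_reads, mouse_model):
        reads, _ = mouse_catalog_reads
        assert all(is_full_length(r, mouse_model) for r in reads)

    def test_polya_removal_fails(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 1.0}, n_reads=5,
                               sub_rate=0, ins_rate=0, del_rate=0,
                               revcomp_frac=0, seed=3)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        for r in reads:
            trimmed = dataclasses.replace(r, sequence=r.sequence[:-cfg.polya_len])
            assert is_full_length(r, mouse_model)
            assert not is_full_length(trimmed, mouse_model)

    def test_background_reads_rarely_pass(self, mouse_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"F": 1.0}, n_reads=1000,
                               background_frac=1.0, seed=19)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        n_fl = sum(is_full_length(r, mouse_model) for r in reads)
        assert n_fl <= 10  # >= 99% rejected

    def test_polya_definition(self):
        assert has_polya("G" * 50 + "A" * 10)
        assert has_polya("G" * 50 + "AAAAACAAAA" + "G" * 3)
        assert not has_polya("G" * 50 + "A" * 5)
        assert not has_polya("ACGT" * 20)


class TestZeroErrorRoundTrip:
    def test_presence_vector_matches_generating_signature(self, mouse_model, barcodes):
        order = [s.segment_id for s in mouse_model.segments]
        for iso in mouse_model.catalog:
            cfg = SimulationConfig(isoform_weights={iso.label: 1.0}, n_reads=1,
                                   sub_rate=0, ins_rate=0, del_rate=0, seed=23)
            reads, _ = simulate_reads(mouse_model, cfg, barcodes)
            vec = screen_read(reads[0], mouse_model)
            assert vec.signature(order) == iso.segments, iso.label
            assert vec.full_length

    def test_human_catalog_round_trip(self, human_model, barcodes):
        order = [s.segment_id for s in human_model.segments]
        for iso in human_model.catalog:
            cfg = SimulationConfig(isoform_weights={iso.label: 1.0}, n_reads=1,
                                   sub_rate=0, ins_rate=0, del_rate=0, seed=29)
            reads, _ = simulate_reads(human_model, cfg, barcodes)
            vec = screen_read(reads[0], human_model)
            assert vec.signature(order) == iso.segments, iso.label

    def test_positions_monotone_in_genomic_order(self, mouse_catalog_reads, mouse_model):
        reads, _ = mouse_catalog_reads
        order = [s.segment_id for s in mouse_model.segments]
        for read in reads[:12]:
            vec = screen_read(read, mouse_model)
            pos = [vec.hits[s].position for s in vec.signature(order)]
            assert pos == sorted(pos)


def _planted_exon_variant(toy):
    """Variant of the toy gene transcribing an 80-nt intronic region."""
    gap_start = toy.exons[1].end + 200
    novel = Exon("N1", gap_start, gap_start + 80, "skippable", "extracellular")
    exons = (toy.exons[0], toy.exons[1], novel, toy.exons[2])
    sig = ("1", "2", "N1", "3")
    return dataclasses.replace(toy, exons=exons,
                               catalog=toy.catalog + (IsoformDef("TN", sig, None),))


class TestDiscoveryScreen:
    def test_annotated_reads_flag_nothing(self, toy_model, barcodes):
        cfg = SimulationConfig(isoform_weights={"T1": 1.0}, n_reads=30,
                               revcomp_frac=0, seed=31)
        reads, _ = simulate_reads(toy_model, cfg, barcodes)
        tiles = discovery_screen(reads, toy_model)
        assert len(tiles.flagged) == 0
        assert tiles.n_full_length > 0

    def test_planted_novel_exon_is_flagged(self, toy_model, barcodes):
        variant = _planted_exon_variant(toy_model)
        cfg = SimulationConfig(isoform_weights={"TN": 1.0}, n_reads=30, seed=37)
        reads, _ = simulate_reads(variant, cfg, barcodes)
        tiles = discovery_screen(reads, toy_model)  # screened against the base model
        novel_iv = (variant.exons[2].start, variant.exons[2].end)
        flagged = tiles.flagged
        assert len(flagged) >= 1
        assert any(row.start < novel_iv[1] and novel_iv[0] < row.end
                   for row in flagged.itertuples())

    def test_empty_read_set(self, toy_model):
        tiles = discovery_screen([], toy_model)
        assert (tiles.table["n_hits"] == 0).all()
        assert len(tiles.flagged) == 0


class TestKoConstruct:
    def test_ko_reads_detected_wildtype_not(self, mouse_model, barcodes):
        marker = egfp_marker()
        ko_cfg = SimulationConfig(isoform_weights={}, n_reads=5, ko_mode=True,
                                  sub_rate=0, ins_rate=0, del_rate=0, seed=41)
        ko_reads, _ = simulate_reads(mouse_model, ko_cfg, barcodes)
        for r in ko_reads:
            assert detect_ko_construct(r, mouse_model, marker)
        wt_cfg = SimulationConfig(isoform_weights={"F": 1.0}, n_reads=5,
                                  sub_rate=0, ins_rate=0, del_rate=0, seed=43)
        wt_reads, _ = simulate_reads(mouse_model, wt_cfg, barcodes)
        for r in wt_reads:
            assert not detect_ko_construct(r, mouse_model, marker)

    def test_ko_sensitivity_at_default_errors(self, mouse_model, barcodes):
        marker = egfp_marker()
        cfg = SimulationConfig(isoform_weights={}, n_reads=500, ko_mode=True, seed=47)
        reads, _ = simulate_reads(mouse_model, cfg, barcodes)
        n_hit = sum(detect_ko_construct(r, mouse_model, marker) for r in reads)
        assert n_hit >= 495  # >= 99%

    def test_empty_marker_rejected(self, mouse_model):
        with pytest.raises(ValueError):
            detect_ko_construct("ACGT", mouse_model, "")
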