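"""Approximate segment detection in long reads.

``detect_segment`` is the core primitive: the minimum edit distance
(substitutions + indels, infix mode — pattern aligned to any substring of
the read, either strand) between a segment and the read, called *present*
when that distance is at most ``floor(max_mismatch_frac * segment length)``
with the published 40% tolerance as default.

On top of it sit the full-length filter (start-exon primer region plus a
polyA tail), the per-read presence vector, the whole-gene tiling discovery
screen for unannotated exonic regions, and the knockout-construct check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .model import Fragment, GeneModel, LongRead, Segment, tile
from .simulate import reverse_complement

__all__ = [
    "SegmentHit",
    "PresenceVector",
    "TileHitTable",
    "detect_segment",
    "best_infix_hit",
    "has_polya",
    "orient_read",
    "is_full_length",
    "screen_read",
    "screen_reads",
    "discovery_screen",
    "detect_ko_construct",
    "DEFAULT_MAX_MISMATCH_FRAC",
]

DEFAULT_MAX_MISMATCH_FRAC = 0.4

# polyA tail definition: within the terminal window, some 10-nt stretch must
# be >= 90% adenine
POLYA_SEARCH_WINDOW = 30
POLYA_RUN = 10
POLYA_MIN_FRAC = 0.9


@dataclass(frozen=True)
class SegmentHit:
    present: bool
    best_distance: int | None
    position: int | None     # start offset of the best match on `strand`
    strand: str = "+"


@dataclass
class PresenceVector:
    """Per-segment presence calls for one read, plus read-level flags."""

    read_id: str
    hits: dict[str, SegmentHit]
    full_length: bool
    ko_construct: bool = False
    strand: str = "+"

    def signature(self, order: Sequence[str]) -> tuple[str, ...]:
        """Present segment ids, in the genomic order given by ``order``."""
        return tuple(s for s in order if s in self.hits and self.hits[s].present)


def _seq_of(read: LongRead | str) -> str:
    return read.sequence if isinstance(read, LongRead) else read


def best_infix_hit(pattern: str, seq: str, k: int = -1) -> tuple[int | None, int | None]:
    """(distance, start) of the best infix alignment of pattern in seq."""
    if not seq or not pattern:
        return None, None
    res = edlib.align(pattern, seq, mode="HW", task="locations", k=k)
    d = res["editDistance"]
    if d == -1:
        return None, None
    return d, res["locations"][0][0]


def detect_segment(read: LongRead | str, segment: Segment | str,
                   max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC) -> SegmentHit:
    """Is the segment present in the read (either strand) at the threshold?

    Present iff the minimum edit distance between the segment and any
    substring of the read is <= floor(max_mismatch_frac * segment length).
    The minimizing distance and offset are returned even when absent.
    """
    pattern = segment.sequence if isinstance(segment, Segment) else segment
    seq = _seq_of(read)
    if not seq:
        return SegmentHit(False, None, None)
    d_f, p_f = best_infix_hit(pattern, seq)
    d_r, p_r = best_infix_hit(pattern, reverse_complement(seq))
    if d_r is not None and (d_f is None or d_r < d_f):
        d, p, strand = d_r, p_r, "-"
    else:
        d, p, strand = d_f, p_f, "+"
    limit = math.floor(max_mismatch_frac * len(pattern))
    return SegmentHit(d is not None and d <= limit, d, p, strand)


def has_polya(seq: str, search_window: int = POLYA_SEARCH_WINDOW,
              run: int = POLYA_RUN, min_frac: float = POLYA_MIN_FRAC) -> bool:
    """A >=``run``-nt window with >=``min_frac`` adenine in the read terminus."""
    tail = seq[-search_window:]
    if len(tail) < run:
        return False
    a = np.frombuffer(tail.encode(), dtype=np.uint8) == ord("A")
    counts = np.convolve(a.astype(np.int32), np.ones(run, dtype=np.int32), "valid")
    return bool((counts >= math.ceil(min_frac * run)).max())


def orient_read(read: LongRead | str, model: GeneModel,
                max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC) -> tuple[str, str]:
    """Return (forward-oriented sequence, emitted strand).

    Orientation is decided by the better primer-region match; when the
    primer is not found on either strand (background reads), by the side
    bearing a polyA tail.
    """
    seq = _seq_of(read)
    if not seq:
        return seq, "+"
    primer = model.primer_sequence
    limit = math.floor(max_mismatch_frac * len(primer))
    d_f, _ = best_infix_hit(primer, seq)
    d_r, _ = best_infix_hit(primer, reverse_complement(seq))
    d_f = len(primer) + 1 if d_f is None else d_f
    d_r = len(primer) + 1 if d_r is None else d_r
    if min(d_f, d_r) <= limit and d_f != d_r:
        return (seq, "+") if d_f < d_r else (reverse_complement(seq), "-")
    if has_polya(seq):
        return seq, "+"
    rc = reverse_complement(seq)
    if has_polya(rc):
        return rc, "-"
    return seq, "+"


def is_full_length(read: LongRead | str, model: GeneModel,
                   max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC) -> bool:
    """Does the read span the start-exon primer region *and* end in polyA?

    This is the denominator condition for all isoform frequencies.
    """
    oriented, _ = orient_read(read, model, max_mismatch_frac)
    if not oriented:
        return False
    primer = model.primer_sequence
    limit = math.floor(max_mismatch_frac * len(primer))
    d, _ = best_infix_hit(primer, oriented, k=limit)
    return d is not None and has_polya(oriented)


def detect_ko_construct(read: LongRead | str, model: GeneModel, marker: str,
                        max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC) -> bool:
    """Knockout-construct read: start-exon 5' UTR followed by the marker."""
    if not marker:
        raise ValueError("marker must be non-empty")
    oriented, _ = orient_read(read, model, max_mismatch_frac)
    if not oriented:
        return False
    utr = model.utr_sequence
    d_u, p_u = best_infix_hit(utr, oriented, k=math.floor(max_mismatch_frac * len(utr)))
    if d_u is None:
        return False
    d_m, p_m = best_infix_hit(marker, oriented, k=math.floor(max_mismatch_frac * len(marker)))
    return d_m is not None and p_m > p_u


def screen_read(read: LongRead | str, model: GeneModel,
                segments: Sequence[Segment] | None = None,
                max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
                ko_marker: str | None = None) -> PresenceVector:
    """Presence vector of one read: all segments, full-length and KO flags.

    The read is first oriented to the gene's forward strand so match
    positions of present segments are comparable across segments.
    """
    if segments is None:
        segments = model.segments
    oriented, strand = orient_read(read, model, max_mismatch_frac)
    hits: dict[str, SegmentHit] = {}
    for seg in segments:
        hits[seg.segment_id] = detect_segment(oriented, seg, max_mismatch_frac)
    primer = model.primer_sequence
    d_p, _ = best_infix_hit(primer, oriented,
                            k=math.floor(max_mismatch_frac * len(primer)))
    full_length = bool(oriented) and d_p is not None and has_polya(oriented)
    ko = bool(ko_marker) and detect_ko_construct(oriented, model, ko_marker,
                                                 max_mismatch_frac)
    read_id = read.read_id if isinstance(read, LongRead) else ""
    return PresenceVector(read_id, hits, full_length, ko, strand)


def screen_reads(reads: Iterable[LongRead], model: GeneModel,
                 max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
                 ko_marker: str | None = None) -> list[PresenceVector]:
    segments = model.segments
    return [screen_read(r, model, segments, max_mismatch_frac, ko_marker)
            for r in reads]


@dataclass
class TileHitTable:
    """Read-hit counts per gene-tiling fragment, with novelty flags."""

    table: pd.DataFrame        # fragment index, start, end, exonic, n_hits, flagged
    n_full_length: int

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def discovery_screen(reads: Iterable[LongRead], model: GeneModel,
                     window: int = 155,
                     max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
                     min_reads: int = 5, min_frac: float = 0.01) -> TileHitTable:
    """Tile the whole gene (introns included) and count read hits per tile.

    Hits are counted over full-length reads only.  Tiles that do not overlap
    any annotated exon yet are detected in at least ``min_reads`` reads and
    in at least ``min_frac`` of full-length reads are flagged as candidate
    novel exonic regions.
    """
    fragments = tile(model, window)
    exon_iv = [(ex.start, ex.end) for ex in model.exons]

    def exonic(f: Fragment) -> bool:
        return any(f.start < e and a < f.end for a, e in exon_iv)

    oriented = []
    for r in reads:
        seq, _ = orient_read(r, model, max_mismatch_frac)
        if seq:
            d, _ = best_infix_hit(model.primer_sequence, seq,
                                  k=math.floor(max_mismatch_frac * len(model.primer_sequence)))
            if d is not None and has_polya(seq):
                oriented.append(seq)
    n_fl = len(oriented)
    threshold = max(min_reads, math.ceil(min_frac * n_fl)) if n_fl else min_reads

    rows = []
    for f in fragments:
        limit = math.floor(max_mismatch_frac * len(f.sequence))
        n_hits = 0
        for seq in oriented:
            d, _ = best_infix_hit(f.sequence, seq, k=limit)
            if d is not None:
                n_hits += 1
        is_ex = exonic(f)
        rows.append({"index": f.index, "start": f.start, "end": f.end,
                     "exonic": is_ex, "n_hits": n_hits,
                     "flagged": (not is_ex) and n_hits >= threshold})
    return TileHitTable(pd.DataFrame(rows), n_fl)
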