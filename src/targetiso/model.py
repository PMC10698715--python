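"""Single-gene splicing model: exons, alternatively spliced segments, tiles.

The unit of analysis is the *segment*: constitutive and skippable exons
contribute their full sequence, while exons with two alternative 3' splice
sites contribute a short form ("a") and a 3' extension ("b").  A transcript
is an ordered concatenation of segment sequences; an isoform is identified
with the set of segments it contains (its *signature*).

Coordinates are 0-based, half-open gene coordinates throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import GeneModelError, ParameterError

__all__ = [
    "Exon",
    "Segment",
    "Fragment",
    "IsoformDef",
    "GeneModel",
    "LongRead",
    "enumerate_segments",
    "tile",
    "isoform_sequence",
]

SPLICE_CLASSES = ("constitutive", "skippable", "extendable")
PROTEIN_SIDES = ("extracellular", "transmembrane", "intracellular", "utr")


@dataclass(frozen=True)
class Exon:
    """One exon of the gene model.

    ``a_part``/``b_part`` are only set for ``extendable`` exons, where the b
    part is the 3' extension produced by the distal alternative 3' splice
    site and must start exactly where the a part ends.
    ``b_introduces_stop`` marks a stop codon inside the b extension (or, for
    a stand-alone stop-bearing exon, inside the exon itself).
    """

    exon_id: str
    start: int
    end: int
    splice_class: str
    protein_side: str
    a_part: tuple[int, int] | None = None
    b_part: tuple[int, int] | None = None
    has_signal_peptide: bool = False
    b_introduces_stop: bool = False

    def __post_init__(self):
        if self.splice_class not in SPLICE_CLASSES:
            raise GeneModelError(f"unknown splice_class {self.splice_class!r}")
        if self.protein_side not in PROTEIN_SIDES:
            raise GeneModelError(f"unknown protein_side {self.protein_side!r}")
        if not 0 <= self.start < self.end:
            raise GeneModelError(f"exon {self.exon_id}: bad interval {self.start}..{self.end}")


@dataclass(frozen=True)
class Segment:
    """An alternatively spliced genomic segment (screening unit).

    ``terminal_if_present`` marks stop-bearing segments that act as the
    transcript 3' end: no further gene segment is expected downstream.
    """

    segment_id: str
    exon_id: str
    start: int
    end: int
    sequence: str
    introduces_stop: bool = False
    terminal_if_present: bool = False
    protein_side: str = "extracellular"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.length <= 0 or len(self.sequence) != self.length:
            raise GeneModelError(f"segment {self.segment_id}: bad length")
        if set(self.sequence) - set("ACGT"):
            raise GeneModelError(f"segment {self.segment_id}: non-ACGT sequence")


@dataclass(frozen=True)
class Fragment:
    """One window of the whole-gene tiling used by the discovery screen."""

    index: int
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class IsoformDef:
    """A catalog isoform: label, ordered segment signature, frequency label.

    ``freq_label`` is the per-isoform percentage printed alongside the
    catalog; it documents the published estimate and seeds simulations, it is
    never an output of this package.
    """

    label: str
    segments: tuple[str, ...]
    freq_label: float | None = None


@dataclass(frozen=True)
class LongRead:
    """A sequenced (or simulated) full-length cDNA read."""

    read_id: str
    sequence: str
    quality: str | None = None
    description: str = ""


@dataclass(frozen=True)
class GeneModel:
    """A single multi-exon gene with splicing and protein-side annotations.

    ``primer_site`` is the gene-specific forward-primer region inside the
    second exon; simulated reads start there and the full-length filter
    requires it.  ``start_codon`` is the gene coordinate of the ATG (inside
    the same exon, downstream of the primer).
    """

    gene_id: str
    length: int
    sequence: str
    exons: tuple[Exon, ...]
    primer_site: tuple[int, int]
    start_codon: int
    tm_exon_id: str
    ig_exon_ids: frozenset[str]
    pdz_segment_id: str
    signal_exon_id: str | None = None
    catalog: tuple[IsoformDef, ...] = ()

    # -- derived accessors -------------------------------------------------

    def exon(self, exon_id: str) -> Exon:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise KeyError(exon_id)

    @property
    def segments(self) -> tuple[Segment, ...]:
        return tuple(enumerate_segments(self))

    @property
    def segment_map(self) -> dict[str, Segment]:
        return {s.segment_id: s for s in enumerate_segments(self)}

    @property
    def segment_order(self) -> dict[str, int]:
        """Genomic rank of each segment id."""
        return {s.segment_id: i for i, s in enumerate(enumerate_segments(self))}

    @property
    def primer_sequence(self) -> str:
        a, b = self.primer_site
        return self.sequence[a:b]

    @property
    def utr_sequence(self) -> str:
        """5' UTR region of the start exon, from the primer to the start codon.

        This is the portion retained in knockout-construct transcripts.
        """
        return self.sequence[self.primer_site[0]: self.start_codon]

    def catalog_by_label(self) -> dict[str, IsoformDef]:
        return {iso.label: iso for iso in self.catalog}

    def validate(self) -> None:
        """Raise :class:`GeneModelError` on any structural violation."""
        if len(self.sequence) != self.length:
            raise GeneModelError("sequence length does not match model length")
        prev_end = 0
        for ex in self.exons:
            if ex.start < prev_end:
                raise GeneModelError(f"exon {ex.exon_id} overlaps or is out of order")
            if ex.end > self.length:
                raise GeneModelError(f"exon {ex.exon_id} exceeds gene length")
            prev_end = ex.end
            if ex.splice_class == "extendable":
                if ex.a_part is None or ex.b_part is None:
                    raise GeneModelError(f"extendable exon {ex.exon_id} lacks a/b parts")
                (a0, a1), (b0, b1) = ex.a_part, ex.b_part
                if (a0, b1) != (ex.start, ex.end) or b0 != a1:
                    raise GeneModelError(
                        f"exon {ex.exon_id}: a/b parts must tile the exon with b as 3' extension"
                    )
        p0, p1 = self.primer_site
        if not any(ex.start <= p0 < p1 <= ex.end for ex in self.exons):
            raise GeneModelError("primer_site does not lie within an exon")
        if not p1 <= self.start_codon:
            raise GeneModelError("start codon must lie downstream of the primer site")
        seg_ids = {s.segment_id for s in enumerate_segments(self)}
        exon_ids = {ex.exon_id for ex in self.exons}
        if self.tm_exon_id not in exon_ids:
            raise GeneModelError(f"tm_exon_id {self.tm_exon_id!r} not in model")
        if self.pdz_segment_id not in seg_ids:
            raise GeneModelError(f"pdz_segment_id {self.pdz_segment_id!r} not in model")
        if not self.ig_exon_ids <= exon_ids:
            raise GeneModelError("ig_exon_ids refer to unknown exons")
        order = self.segment_order
        for iso in self.catalog:
            unknown = [s for s in iso.segments if s not in seg_ids]
            if unknown:
                raise GeneModelError(f"isoform {iso.label}: unknown segments {unknown}")
            ranks = [order[s] for s in iso.segments]
            if ranks != sorted(ranks):
                raise GeneModelError(f"isoform {iso.label}: signature not in genomic order")


def enumerate_segments(model: GeneModel) -> list[Segment]:
    """List the gene's alternatively spliced segments in genomic order.

    Constitutive and skippable exons contribute one segment each (the full
    exon); extendable exons contribute their a part and their b extension
    ("a" before "b").  Stop-bearing segments are flagged terminal.
    """
    segments: list[Segment] = []
    for ex in model.exons:
        if ex.splice_class == "extendable":
            if ex.a_part is None or ex.b_part is None:
                raise GeneModelError(f"extendable exon {ex.exon_id} lacks a/b parts")
            (a0, a1), (b0, b1) = ex.a_part, ex.b_part
            segments.append(
                Segment(f"{ex.exon_id}a", ex.exon_id, a0, a1, model.sequence[a0:a1],
                        protein_side=ex.protein_side)
            )
            segments.append(
                Segment(f"{ex.exon_id}b", ex.exon_id, b0, b1, model.sequence[b0:b1],
                        introduces_stop=ex.b_introduces_stop,
                        terminal_if_present=ex.b_introduces_stop,
                        protein_side=ex.protein_side)
            )
        else:
            segments.append(
                Segment(ex.exon_id, ex.exon_id, ex.start, ex.end,
                        model.sequence[ex.start:ex.end],
                        introduces_stop=ex.b_introduces_stop,
                        terminal_if_present=ex.b_introduces_stop,
                        protein_side=ex.protein_side)
            )
    return segments


def tile(model: GeneModel, window: int = 155) -> list[Fragment]:
    """Partition the gene into consecutive ``window``-bp fragments.

    The final fragment may be shorter; concatenating all fragment sequences
    reconstructs the gene, so the fragment count is ``ceil(length/window)``.
    """
    if window <= 0:
        raise ParameterError(f"window must be >= 1, got {window}")
    frags = []
    for i in range(math.ceil(model.length / window)):
        a = i * window
        b = min(model.length, a + window)
        frags.append(Fragment(i, a, b, model.sequence[a:b]))
    return frags


def isoform_sequence(model: GeneModel, segments: Sequence[str]) -> str:
    """Spliced transcript sequence for an ordered segment signature."""
    smap = model.segment_map
    try:
        return "".join(smap[s].sequence for s in segments)
    except KeyError as exc:
        raise GeneModelError(f"unknown segment {exc.args[0]!r} in signature") from exc
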