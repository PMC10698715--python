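"""Translation and protein-level classification of isoforms.

Each consistent isoform is translated from the start codon in the start
exon and classified by where translation terminates relative to the
transmembrane-encoding exon:

* ``secreted``     — the terminal stop lies in a segment genomically
                     upstream of the transmembrane exon, so the protein
                     retains only extracellular (Ig) domains;
* ``TM_short``     — the transcript ends at the stop-bearing extension
                     downstream of the transmembrane exon (short
                     intracellular tail, no PDZ-binding motif);
* ``TM_long_PDZ``  — the PDZ-encoding terminal segment is included (long
                     intracellular tail ending in the PDZ-binding motif).

Signal-peptide status is a gene-model annotation (presence of the
signal-peptide exon), not a sequence prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ClassificationError, GeneModelError
from .calling import IsoformTable
from .model import GeneModel, IsoformDef, isoform_sequence

__all__ = [
    "ProteinClassification",
    "translate_isoform",
    "stop_segment",
    "classify_isoform",
    "classify_catalog",
    "class_summary",
    "CLASSES",
]

CLASSES = ("TM_long_PDZ", "TM_short", "secreted")


@dataclass(frozen=True)
class ProteinClassification:
    isoform_label: str
    klass: str
    n_ig_domains: int
    has_cleavable_signal_peptide: bool
    terminal_segment: str


def _signature_of(isoform: IsoformDef | Sequence[str]) -> tuple[str, ...]:
    if isinstance(isoform, IsoformDef):
        return isoform.segments
    return tuple(isoform)


def translate_isoform(isoform: IsoformDef | Sequence[str], model: GeneModel) -> str:
    """Amino-acid sequence from the start codon to the first stop codon."""
    signature = _signature_of(isoform)
    if not signature:
        raise GeneModelError("cannot translate an empty signature")
    mrna = isoform_sequence(model, signature)
    offset = model.start_codon - model.segment_map[signature[0]].start
    if offset < 0 or mrna[offset:offset + 3] != "ATG":
        raise GeneModelError("no start codon at the expected position")
    return str(Seq(mrna[offset:]).translate(to_stop=True))


def stop_segment(isoform: IsoformDef | Sequence[str], model: GeneModel) -> str:
    """Segment id containing the first in-frame stop codon of the isoform."""
    signature = _signature_of(isoform)
    mrna = isoform_sequence(model, signature)
    offset = model.start_codon - model.segment_map[signature[0]].start
    aa = translate_isoform(signature, model)
    stop_nt = offset + 3 * len(aa)      # first base of the stop codon
    if mrna[stop_nt:stop_nt + 3] not in ("TAA", "TAG", "TGA"):
        raise ClassificationError("translation runs off the transcript without a stop")
    smap = model.segment_map
    pos = 0
    for sid in signature:
        nxt = pos + smap[sid].length
        if stop_nt < nxt:
            return sid
        pos = nxt
    raise ClassificationError("stop codon position outside the transcript")


def classify_isoform(isoform: IsoformDef | Sequence[str], model: GeneModel) -> ProteinClassification:
    """Structural classification of one (consistent) isoform signature.

    Decided from the signature's terminal segment relative to the
    transmembrane exon; agreement with the translation-based stop position
    is an invariant checked in the test-suite, not assumed here.
    """
    signature = _signature_of(isoform)
    label = isoform.label if isinstance(isoform, IsoformDef) else "+".join(signature)
    if not signature:
        raise ClassificationError("empty signature")
    smap = model.segment_map
    order = model.segment_order
    unknown = [s for s in signature if s not in smap]
    if unknown:
        raise GeneModelError(f"unknown segments in signature: {unknown}")

    tm_rank = min(order[s.segment_id] for s in model.segments
                  if s.exon_id == model.tm_exon_id)
    terminal = signature[-1]
    term_seg = smap[terminal]

    if term_seg.introduces_stop and order[terminal] < tm_rank:
        klass = "secreted"
    elif term_seg.introduces_stop and order[terminal] > tm_rank:
        klass = "TM_short"
    elif model.pdz_segment_id in signature:
        klass = "TM_long_PDZ"
    else:
        raise ClassificationError(
            f"isoform {label}: terminal segment {terminal!r} matches no protein class"
        )

    exons_present = {smap[s].exon_id for s in signature}
    n_ig = len(model.ig_exon_ids & exons_present)
    has_sp = (model.signal_exon_id is not None
              and model.signal_exon_id in exons_present)
    return ProteinClassification(label, klass, n_ig, has_sp, terminal)


def classify_catalog(model: GeneModel) -> dict[str, ProteinClassification]:
    """Classification of every catalog isoform, keyed by label."""
    return {iso.label: classify_isoform(iso, model) for iso in model.catalog}


def class_summary(table: IsoformTable,
                  classifications: Mapping[str, ProteinClassification]) -> pd.DataFrame:
    """Cumulative frequency per protein class over a called isoform table."""
    missing = [lbl for lbl in table.table["label"] if lbl not in classifications]
    if missing:
        raise ClassificationError(f"isoforms without classification: {missing}")
    sums = {k: 0.0 for k in CLASSES}
    counts = {k: 0 for k in CLASSES}
    for row in table.table.itertuples():
        k = classifications[row.label].klass
        sums[k] += row.frequency_pct
        counts[k] += row.count
    return pd.DataFrame(
        [{"class": k, "n_reads": counts[k], "frequency_pct": sums[k]} for k in CLASSES],
        columns=["class", "n_reads", "frequency_pct"],
    )
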