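"""Isoform calling from presence vectors and frequency estimation.

A read's *signature* is the ordered set of segments detected in it.
Signatures matching a catalog entry exactly inherit its label; unmatched
but internally consistent signatures get a stable ``NOVEL:<hash>`` label.
Two consistency rules reflect the splicing grammar: a stop-bearing terminal
segment admits nothing downstream of it, and a 3' extension ("b") cannot be
present without its parent short form ("a").  Inconsistent reads are
flagged and excluded from frequency denominators.

Frequencies are percentages of *full-length consistent* reads — reads
containing the start-exon primer region and a polyA tail.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import GeneModelError, ParameterError
from .model import GeneModel
from .screen import PresenceVector

__all__ = [
    "IsoformCall",
    "IsoformTable",
    "call_isoform",
    "call_isoforms",
    "estimate_frequencies",
    "cumulative_segment_frequency",
    "novel_label",
]


@dataclass(frozen=True)
class IsoformCall:
    read_id: str
    signature: tuple[str, ...]
    label: str
    consistent: bool


def novel_label(signature: Sequence[str]) -> str:
    """Stable label for a non-catalog signature (identical input, identical label)."""
    digest = hashlib.sha1("+".join(signature).encode()).hexdigest()[:8]
    return f"NOVEL:{digest}"


def _check_consistency(signature: Sequence[str], model: GeneModel) -> bool:
    smap = model.segment_map
    order = model.segment_order
    present = set(signature)
    for sid in signature:
        seg = smap[sid]
        if seg.terminal_if_present:
            if any(order[o] > order[sid] for o in present if o != sid):
                return False
        if sid.endswith("b") and sid[:-1] + "a" in smap and sid[:-1] + "a" not in present:
            return False
    return True


def call_isoform(vector: PresenceVector, model: GeneModel) -> IsoformCall:
    """Assign a catalog label (or a stable NOVEL label) to one presence vector."""
    order_list = [s.segment_id for s in model.segments]
    known = set(order_list)
    foreign = set(vector.hits) - known
    if foreign:
        raise GeneModelError(
            f"presence vector contains segments not in this gene model: {sorted(foreign)}"
        )
    signature = vector.signature(order_list)
    consistent = _check_consistency(signature, model)
    by_sig = {iso.segments: iso.label for iso in model.catalog}
    label = by_sig.get(signature, novel_label(signature))
    return IsoformCall(vector.read_id, signature, label, consistent)


def call_isoforms(vectors: Iterable[PresenceVector], model: GeneModel) -> list[IsoformCall]:
    return [call_isoform(v, model) for v in vectors]


@dataclass
class IsoformTable:
    """Per-isoform counts and frequencies over full-length consistent reads."""

    table: pd.DataFrame            # label, signature, count, frequency_pct
    denominator: int               # number of eligible reads

    def frequency(self, label: str) -> float:
        rows = self.table[self.table["label"] == label]
        return float(rows["frequency_pct"].iloc[0]) if len(rows) else 0.0

    def signatures(self) -> dict[str, tuple[str, ...]]:
        return {row.label: tuple(s for s in row.signature.split("+") if s)
                for row in self.table.itertuples()}


def estimate_frequencies(calls: Iterable[IsoformCall],
                         vectors: Iterable[PresenceVector],
                         min_support: int = 1) -> IsoformTable:
    """Isoform frequency table over full-length consistent calls.

    ``frequency(i) = 100 * count(i) / total`` where the total counts reads
    that pass the full-length filter, are consistent, and are not
    knockout-construct reads.  Zero eligible reads yield an empty table with
    an explicit zero denominator.
    """
    flags = {v.read_id: v for v in vectors}
    counts: dict[str, int] = {}
    sigs: dict[str, tuple[str, ...]] = {}
    total = 0
    for call in calls:
        v = flags.get(call.read_id)
        if v is None or not v.full_length or v.ko_construct or not call.consistent:
            continue
        if not call.signature:
            # no gene segment detected at all: not a gene transcript
            continue
        total += 1
        counts[call.label] = counts.get(call.label, 0) + 1
        sigs[call.label] = call.signature
    rows = [{"label": lbl, "signature": "+".join(sigs[lbl]), "count": n,
             "frequency_pct": 100.0 * n / total}
            for lbl, n in counts.items() if n >= min_support]
    df = pd.DataFrame(rows, columns=["label", "signature", "count", "frequency_pct"])
    df = df.sort_values(["count", "label"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return IsoformTable(df, total)


def cumulative_segment_frequency(table: IsoformTable, segment_id: str,
                                 model: GeneModel) -> float:
    """Summed frequency of all called isoforms whose signature has the segment."""
    if segment_id not in {s.segment_id for s in model.segments}:
        raise ParameterError(f"unknown segment {segment_id!r}")
    total = 0.0
    for row in table.table.itertuples():
        if segment_id in row.signature.split("+"):
            total += row.frequency_pct
    return total
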