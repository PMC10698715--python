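"""Barcode demultiplexing: assign each read to a sample by its 16-nt barcode.

The metric is Hamming distance over a sliding window (no indels inside the
barcode), scanned over the first and last 50 nt of the read on both strands.
A read is assigned only when a *unique* barcode achieves the minimum
distance and that distance is within the mismatch budget (default 2);
ambiguous best hits are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model import LongRead
from .simulate import BarcodeSet, reverse_complement

__all__ = ["UNASSIGNED", "DemuxResult", "DemuxSummary", "assign_barcode", "demux_report"]

UNASSIGNED = "unassigned"
TERMINUS_LEN = 50


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    assigned_sample: str | None      # None => unassigned
    best_distance: int | None        # None for reads too short to scan
    n_best: int

    @property
    def assigned(self) -> bool:
        return self.assigned_sample is not None


def _scan_regions(seq: str, terminus_len: int) -> list[str]:
    regions = []
    for s in (seq, reverse_complement(seq)):
        if len(s) <= 2 * terminus_len:
            regions.append(s)
        else:
            regions.append(s[:terminus_len])
            regions.append(s[-terminus_len:])
    return regions


def assign_barcode(read: LongRead | str, barcodes: BarcodeSet,
                   max_mismatches: int = 2,
                   terminus_len: int = TERMINUS_LEN) -> DemuxResult:
    """Best sliding-window Hamming match of any barcode near either read end.

    Returns the minimum distance over all barcode placements, the number of
    barcodes achieving it, and the assignment (unique best barcode with
    distance <= ``max_mismatches``, else unassigned).
    """
    seq = read.sequence if isinstance(read, LongRead) else read
    read_id = read.read_id if isinstance(read, LongRead) else ""
    sample_ids = list(barcodes.sample_ids)
    bc_len = len(next(iter(barcodes.barcodes.values())))
    if len(seq) < bc_len:
        return DemuxResult(read_id, None, None, 0)

    bc_arr = np.array([np.frombuffer(barcodes.barcodes[s].encode(), dtype=np.uint8)
                       for s in sample_ids])
    best = np.full(len(sample_ids), bc_len + 1, dtype=np.int64)
    for region in _scan_regions(seq, terminus_len):
        arr = np.frombuffer(region.encode(), dtype=np.uint8)
        if arr.size < bc_len:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, bc_len)
        # (n_windows, n_barcodes) mismatch counts
        mm = (windows[:, None, :] != bc_arr[None, :, :]).sum(axis=2)
        np.minimum(best, mm.min(axis=0), out=best)

    best_distance = int(best.min())
    hits = np.flatnonzero(best == best_distance)
    n_best = int(hits.size)
    if best_distance <= max_mismatches and n_best == 1:
        return DemuxResult(read_id, sample_ids[hits[0]], best_distance, 1)
    return DemuxResult(read_id, None, best_distance, n_best)


@dataclass(frozen=True)
class DemuxSummary:
    per_sample: dict[str, int]
    n_total: int
    n_assigned: int

    @property
    def n_unassigned(self) -> int:
        return self.n_total - self.n_assigned

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else 0.0

    @property
    def unassigned_fraction(self) -> float:
        return self.n_unassigned / self.n_total if self.n_total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "n_reads": n} for s, n in sorted(self.per_sample.items())]
        rows.append({"sample": UNASSIGNED, "n_reads": self.n_unassigned})
        return pd.DataFrame(rows, columns=["sample", "n_reads"])


def demux_report(results: Iterable[DemuxResult]) -> DemuxSummary:
    """Per-sample counts plus assigned/unassigned fractions."""
    per_sample: dict[str, int] = {}
    n_total = n_assigned = 0
    for r in results:
        n_total += 1
        if r.assigned:
            n_assigned += 1
            per_sample[r.assigned_sample] = per_sample.get(r.assigned_sample, 0) + 1
    return DemuxSummary(per_sample, n_total, n_assigned)
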