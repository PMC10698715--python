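"""Independent brute-force oracles used to pin implementation semantics.

These are deliberately written with different algorithms and data paths
than the package (dynamic programming by hand, exhaustive scans) and are
only ever used as ground truth in tests.
"""

from __future__ import annotations

import numpy as np

_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def infix_edit_distance(pattern: str, text: str) -> int:
    """Minimum edit distance of pattern to any substring of text.

    Classic semi-global DP: free leading/trailing gaps in the text.
    """
    if not pattern:
        return 0
    if not text:
        return len(pattern)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    n = t.size
    prev = np.zeros(n + 1, dtype=np.int64)   # empty pattern: free start
    idx = np.arange(n + 1, dtype=np.int64)
    for i in range(p.size):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i + 1
        sub = prev[:-1] + (t != p[i])        # match/mismatch
        dele = prev[1:] + 1                  # skip pattern char
        cur[1:] = np.minimum(sub, dele)
        # left-to-right relaxation (insertion of text chars), vectorized:
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev.min())


def infix_edit_distance_both_strands(pattern: str, text: str) -> int:
    return min(infix_edit_distance(pattern, text),
               infix_edit_distance(pattern, revcomp(text)))


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def demux_oracle(seq: str, barcodes: dict[str, str], max_mismatches: int,
                 terminus_len: int = 50):
    """Exhaustive sliding Hamming over both strands of both read termini.

    Returns (assigned_sample_or_None, best_distance_or_None, n_best).
    """
    bc_len = len(next(iter(barcodes.values())))
    if len(seq) < bc_len:
        return None, None, 0
    regions = []
    for s in (seq, revcomp(seq)):
        if len(s) <= 2 * terminus_len:
            regions.append(s)
        else:
            regions.append(s[:terminus_len])
            regions.append(s[-terminus_len:])
    best = {sid: bc_len + 1 for sid in barcodes}
    for sid, bc in barcodes.items():
        for region in regions:
            for off in range(len(region) - bc_len + 1):
                best[sid] = min(best[sid], hamming(region[off:off + bc_len], bc))
    bmin = min(best.values())
    winners = [sid for sid, d in best.items() if d == bmin]
    if bmin <= max_mismatches and len(winners) == 1:
        return winners[0], bmin, 1
    return None, bmin, len(winners)


def origin_oracle(tree, carriers: set[str]) -> str:
    """Exhaustive scan: smallest clade whose tip set contains all carriers."""
    best_node, best_size = None, None
    for node in tree.preorder_node_iter():
        tips = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
        if carriers <= tips and (best_size is None or len(tips) < best_size):
            best_node, best_size = node, len(tips)
    assert best_node is not None
    if best_node.is_leaf():
        return best_node.taxon.label
    return (best_node.taxon.label if best_node.taxon is not None
            and best_node.taxon.label else best_node.label) or ""
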