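"""Seeded gene-model fixtures reproducing the published mouse and human
Kirrel3 exon topologies with synthetic sequences.

The published topology (exon identities, extendable exons, stop-bearing
extensions, protein sides, isoform catalogs and their frequency labels) is
encoded exactly; nucleotide sequences are synthetic, generated from the
seed.  Two properties are enforced at build time so that presence calls at
the 40% edit-distance threshold are well-posed on simulated reads:

* pairwise global edit distance between any two segments is at least 50% of
  the shorter segment, and
* every segment, aligned in infix mode against every catalog transcript that
  does *not* contain it, scores a distance above 43% of its own length.

Both are achieved by rejection-resampling individual segments, which keeps
fixture construction deterministic for a given seed.

Coding segments are whole numbers of codons drawn from the 61 sense codons,
so reading frame is preserved across every catalog segment combination and
the only in-frame stop codons are the ones deliberately placed in
stop-bearing segments (and at the end of the terminal exon).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import edlib
import numpy as np

from .errors import GeneModelError
from .model import Exon, GeneModel, IsoformDef

__all__ = [
    "make_mouse_fixture",
    "make_human_fixture",
    "make_toy_model",
    "MOUSE_GENE_LENGTH",
    "HUMAN_GENE_LENGTH",
]

MOUSE_GENE_LENGTH = 550_823
HUMAN_GENE_LENGTH = 584_513

# All coding segments are 70 codons; long enough that a 40% edit-distance
# screen has empirically negligible random-match probability (see methods).
SEG_NT = 210
UTR_LEN = 70          # 5' UTR inside the start exon (exon 2)
PRIMER_OFFSET = 0     # reads begin at the very start of the start exon
PRIMER_LEN = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in _STOPS]

# pairwise / cross-transcript distinguishability thresholds (fractions of
# the shorter segment / the segment length respectively)
_PAIR_MIN_FRAC = 0.50
_CROSS_MIN_FRAC = 0.43


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _coding(rng: np.random.Generator, n_nt: int, stop_codon_at: int | None = None,
            final_stop: bool = False) -> str:
    """Random in-frame coding sequence of ``n_nt`` (multiple of 3).

    ``stop_codon_at`` places a TAA at that codon index (0-based);
    ``final_stop`` places a TAA as the last codon.
    """
    assert n_nt % 3 == 0
    n = n_nt // 3
    codons = [_SENSE[i] for i in rng.integers(0, len(_SENSE), size=n)]
    if stop_codon_at is not None:
        codons[stop_codon_at] = "TAA"
    if final_stop:
        codons[-1] = "TAA"
    return "".join(codons)


# ---------------------------------------------------------------------------
# topology tables
#
# (exon_id, splice_class, protein_side, length_nt, flags)
# flags: S = signal peptide, X = stop in b extension (or in the exon itself
# for a stand-alone stop exon)
# ---------------------------------------------------------------------------

_MOUSE_EXONS = [
    ("1", "constitutive", "utr", 200, ""),
    ("2", "constitutive", "extracellular", UTR_LEN + SEG_NT, ""),
    # predicted exons 3-5: in the gene model, absent from the catalog
    ("3", "skippable", "extracellular", SEG_NT, ""),
    ("4", "skippable", "extracellular", SEG_NT, ""),
    ("5", "skippable", "extracellular", SEG_NT, ""),
    ("6", "skippable", "extracellular", SEG_NT, "S"),
    ("7", "constitutive", "extracellular", SEG_NT, ""),
    ("8", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("9", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("10", "skippable", "extracellular", SEG_NT, "X"),   # stand-alone stop exon
    ("11", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("12", "constitutive", "extracellular", SEG_NT, ""),
    ("13", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("14", "constitutive", "extracellular", SEG_NT, ""),
    ("15", "constitutive", "extracellular", SEG_NT, ""),
    ("16", "constitutive", "extracellular", SEG_NT, ""),
    ("17", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("18", "skippable", "extracellular", SEG_NT, ""),
    ("19", "extendable", "transmembrane", 2 * SEG_NT, ""),   # 19b: +25 aa, no stop
    ("20", "extendable", "intracellular", 2 * SEG_NT, "X"),  # 20b: short tail, stop
    ("21", "constitutive", "intracellular", SEG_NT, ""),
    ("22", "skippable", "intracellular", SEG_NT, ""),        # PDZ-binding terminus
]

# constitutive backbone of every mouse catalog isoform, exon 2 .. exon 21
_M_CORE_A = ["2", "7", "8a", "9a", "11a", "12", "13a", "14", "15", "16", "17a"]
_M_CORE_B = ["19a", "20a"]


def _mouse_tm_signature(e6: bool, e18: bool, e19b: bool, terminal: str) -> tuple[str, ...]:
    sig = ["2"] + (["6"] if e6 else []) + _M_CORE_A[1:]
    if e18:
        sig.append("18")
    sig.append("19a")
    if e19b:
        sig.append("19b")
    sig.append("20a")
    if terminal == "22":
        sig += ["21", "22"]
    else:  # short-tail terminus
        sig.append("20b")
    return tuple(sig)


def _mouse_secreted_signature(terminal: str) -> tuple[str, ...]:
    upstream = {"8b": ["2", "6", "7", "8a"],
                "9b": ["2", "6", "7", "8a", "9a"],
                "10": ["2", "6", "7", "8a", "9a"],
                "11b": ["2", "6", "7", "8a", "9a", "11a"],
                "13b": ["2", "6", "7", "8a", "9a", "11a", "12", "13a"],
                "17b": ["2", "6", "7", "8a", "9a", "11a", "12", "13a",
                        "14", "15", "16", "17a"]}[terminal]
    return tuple(upstream + [terminal]) if terminal != "10" else tuple(upstream + ["10"])


# 13 transmembrane isoforms (8 long-tailed ending in exon 22, 5 short-tailed
# ending at 20b) and 6 secreted isoforms, 19 in total.  Letters follow the
# published catalog (isoform E, the exon-5 transcript, was never seen in
# hippocampus and is not in the catalog).  freq labels sum to 100 with the
# printed aggregates: 95% exon 22, ~1% short-tailed, 4% secreted.
_MOUSE_CATALOG = [
    ("A", _mouse_tm_signature(True, True, False, "22"), 25.0),
    ("B", _mouse_tm_signature(True, True, True, "22"), 18.0),
    ("C", _mouse_tm_signature(True, False, True, "22"), 14.0),
    ("D", _mouse_tm_signature(False, True, False, "22"), 12.0),
    ("F", _mouse_tm_signature(True, False, False, "22"), 11.0),
    ("G", _mouse_tm_signature(False, False, False, "22"), 8.0),
    ("H", _mouse_tm_signature(False, True, True, "22"), 4.0),
    ("I", _mouse_tm_signature(False, False, True, "22"), 3.0),
    ("J", _mouse_tm_signature(True, False, False, "20b"), 0.2),
    ("K", _mouse_tm_signature(True, True, False, "20b"), 0.3),
    ("L", _mouse_tm_signature(True, True, True, "20b"), 0.2),
    ("M", _mouse_tm_signature(False, True, False, "20b"), 0.15),
    ("N", _mouse_tm_signature(True, False, True, "20b"), 0.15),
    ("O", _mouse_secreted_signature("8b"), 0.5),
    ("P", _mouse_secreted_signature("9b"), 0.5),
    ("Q", _mouse_secreted_signature("10"), 0.5),
    ("R", _mouse_secreted_signature("11b"), 0.5),
    ("S", _mouse_secreted_signature("13b"), 1.0),
    ("T", _mouse_secreted_signature("17b"), 1.0),
]

_HUMAN_EXONS = [
    ("1", "constitutive", "utr", 200, ""),
    ("2", "constitutive", "extracellular", UTR_LEN + SEG_NT, ""),
    ("3", "skippable", "extracellular", SEG_NT, "S"),
    ("4", "constitutive", "extracellular", SEG_NT, ""),
    ("5", "constitutive", "extracellular", SEG_NT, ""),
    ("6", "constitutive", "extracellular", SEG_NT, ""),
    ("7", "constitutive", "extracellular", SEG_NT, ""),
    ("8", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("9", "constitutive", "extracellular", SEG_NT, ""),
    ("10", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("11", "constitutive", "extracellular", SEG_NT, ""),
    ("12", "extendable", "extracellular", 2 * SEG_NT, "X"),
    ("13", "constitutive", "extracellular", SEG_NT, ""),
    ("14", "extendable", "extracellular", 2 * SEG_NT, ""),
    ("15", "skippable", "extracellular", SEG_NT, ""),
    ("16", "constitutive", "transmembrane", SEG_NT, ""),
    ("17", "extendable", "intracellular", 2 * SEG_NT, ""),
    ("18", "skippable", "intracellular", SEG_NT, ""),     # great-ape-specific exon
    ("19", "extendable", "intracellular", 2 * SEG_NT, "X"),  # 19b: short tail, stop
    ("20", "constitutive", "intracellular", SEG_NT, ""),
    ("21", "skippable", "intracellular", SEG_NT, ""),     # PDZ-binding terminus
]

_H_CORE = ["2", "4", "5", "6", "7", "8a", "9", "10a", "11", "12a", "13", "14a"]


def _human_tm_signature(e3: bool, e15: bool, e14b: bool, e17b: bool, e18: bool,
                        terminal: str) -> tuple[str, ...]:
    sig = ["2"] + (["3"] if e3 else []) + _H_CORE[1:]
    if e14b:
        sig.insert(sig.index("14a") + 1, "14b")
    if e15:
        sig.append("15")
    sig += ["16", "17a"]
    if e17b:
        sig.append("17b")
    if e18:
        sig.append("18")
    sig.append("19a")
    if terminal == "21":
        sig += ["20", "21"]
    else:
        sig.append("19b")
    return tuple(sig)


_HUMAN_CATALOG = [
    ("1", _human_tm_signature(True, True, False, False, False, "21"), 30.0),
    ("2", _human_tm_signature(True, True, False, True, False, "21"), 20.0),
    ("3", _human_tm_signature(True, False, False, False, False, "21"), 14.0),
    ("4", _human_tm_signature(False, True, False, False, False, "21"), 11.0),
    ("5", _human_tm_signature(True, True, False, False, True, "21"), 8.0),
    ("6", _human_tm_signature(True, False, True, True, False, "21"), 7.0),
    ("7", _human_tm_signature(False, False, False, False, False, "21"), 5.5),
    ("8", _human_tm_signature(True, True, False, False, False, "19b"), 1.5),
    ("9", ("2", "3", "4", "5", "6", "7", "8a", "8b"), 1.0),
    ("10", ("2", "3", "4", "5", "6", "7", "8a", "9", "10a", "10b"), 1.0),
    ("11", ("2", "3", "4", "5", "6", "7", "8a", "9", "10a", "11", "12a", "12b"), 1.0),
]


# ---------------------------------------------------------------------------
# sequence assignment with distinguishability enforcement
# ---------------------------------------------------------------------------

def _segment_layout(exons) -> list[tuple[str, str, int]]:
    """(segment_id, exon_id, length) in genomic order."""
    out = []
    for exon_id, sclass, _side, length, _flags in exons:
        if sclass == "extendable":
            out.append((f"{exon_id}a", exon_id, SEG_NT))
            out.append((f"{exon_id}b", exon_id, SEG_NT))
        else:
            out.append((exon_id, exon_id, length))
    return out


def _draw_segment(rng, seg_id, exon_id, length, flags, pdz_segment_id):
    """Draw one segment sequence honouring coding structure and stop flags."""
    if exon_id == "1":
        return _random_dna(rng, length)
    if exon_id == "2":
        utr = _random_dna(rng, UTR_LEN)
        return utr + "ATG" + _coding(rng, SEG_NT - 3)
    stop_b = "X" in flags
    if seg_id.endswith("b") and stop_b:
        return _coding(rng, length, stop_codon_at=5)     # short peptide, then stop
    if not seg_id.endswith("a") and not seg_id.endswith("b") and stop_b:
        return _coding(rng, length, stop_codon_at=3)     # stand-alone stop exon
    if seg_id == pdz_segment_id:
        return _coding(rng, length, final_stop=True)     # canonical terminus
    return _coding(rng, length)


def _build_fixture(seed: int, gene_id: str, gene_length: int, exon_table,
                   catalog_rows, tm_exon_id: str, ig_exon_ids, pdz_segment_id: str,
                   signal_exon_id: str) -> GeneModel:
    rng = np.random.default_rng(seed)
    layout = _segment_layout(exon_table)
    flags_by_exon = {row[0]: row[4] for row in exon_table}

    seqs: dict[str, str] = {}
    for seg_id, exon_id, length in layout:
        seqs[seg_id] = _draw_segment(rng, seg_id, exon_id, length,
                                     flags_by_exon[exon_id], pdz_segment_id)

    catalog_sigs = [tuple(sig) for _label, sig, _f in catalog_rows]

    def transcript(sig):
        return "".join(seqs[s] for s in sig)

    # rejection-resample until segments are mutually distinguishable and no
    # segment infix-matches a transcript it is not part of
    for _round in range(200):
        offender = None
        ids = [seg_id for seg_id, _e, _l in layout]
        for i, j in itertools.combinations(range(len(ids)), 2):
            a, b = seqs[ids[i]], seqs[ids[j]]
            d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            if d < _PAIR_MIN_FRAC * min(len(a), len(b)):
                offender = ids[j]
                break
        if offender is None:
            for seg_id in ids:
                pat = seqs[seg_id]
                limit = int(_CROSS_MIN_FRAC * len(pat))
                for sig in catalog_sigs:
                    if seg_id in sig:
                        continue
                    d = edlib.align(pat, transcript(sig), mode="HW",
                                    task="distance", k=limit)["editDistance"]
                    if d != -1:  # within `limit`: too similar
                        offender = seg_id
                        break
                if offender:
                    break
        if offender is None:
            break
        exon_id = next(e for s, e, _l in layout if s == offender)
        length = next(l for s, _e, l in layout if s == offender)
        seqs[offender] = _draw_segment(rng, offender, exon_id, length,
                                       flags_by_exon[exon_id], pdz_segment_id)
    else:
        raise GeneModelError(f"fixture seed {seed}: could not satisfy "
                             "segment-distinguishability constraints")

    # place exons on the gene with evenly sized introns
    exonic = sum(row[3] for row in exon_table)
    n_gaps = len(exon_table) + 1
    gap = (gene_length - exonic) // n_gaps
    exons = []
    pos = gap
    seq_parts = []
    cursor = 0
    for exon_id, sclass, side, length, flags in exon_table:
        start, end = pos, pos + length
        a_part = b_part = None
        if sclass == "extendable":
            a_part = (start, start + SEG_NT)
            b_part = (start + SEG_NT, end)
            exon_seq = seqs[f"{exon_id}a"] + seqs[f"{exon_id}b"]
        else:
            exon_seq = seqs[exon_id]
        exons.append(Exon(exon_id, start, end, sclass, side, a_part, b_part,
                          has_signal_peptide="S" in flags,
                          b_introduces_stop="X" in flags))
        seq_parts.append(_random_dna(rng, start - cursor))
        seq_parts.append(exon_seq)
        cursor = end
        pos = end + gap
    seq_parts.append(_random_dna(rng, gene_length - cursor))
    gene_seq = "".join(seq_parts)
    assert len(gene_seq) == gene_length

    exon2 = next(ex for ex in exons if ex.exon_id == "2")
    model = GeneModel(
        gene_id=gene_id,
        length=gene_length,
        sequence=gene_seq,
        exons=tuple(exons),
        primer_site=(exon2.start + PRIMER_OFFSET, exon2.start + PRIMER_OFFSET + PRIMER_LEN),
        start_codon=exon2.start + UTR_LEN,
        tm_exon_id=tm_exon_id,
        ig_exon_ids=frozenset(ig_exon_ids),
        pdz_segment_id=pdz_segment_id,
        signal_exon_id=signal_exon_id,
        catalog=tuple(IsoformDef(lbl, tuple(sig), f) for lbl, sig, f in catalog_rows),
    )
    model.validate()
    return model


@lru_cache(maxsize=8)
def make_mouse_fixture(seed: int) -> GeneModel:
    """Mouse fixture: 22 exons, 29 segments, 19-isoform catalog.

    Extendable exons 8, 9, 11, 13, 17, 19 and 20; stop-bearing extensions
    8b, 9b, 11b, 13b, 17b and 20b plus the stand-alone stop exon 10;
    skippable exons 6, 18 and 22; predicted exons 3-5 are modeled but appear
    in no catalog isoform.
    """
    return _build_fixture(
        seed, "Kirrel3_mouse_synthetic", MOUSE_GENE_LENGTH, _MOUSE_EXONS,
        _MOUSE_CATALOG, tm_exon_id="19",
        ig_exon_ids=("7", "9", "11", "13", "15"),
        pdz_segment_id="22", signal_exon_id="6",
    )


@lru_cache(maxsize=8)
def make_human_fixture(seed: int) -> GeneModel:
    """Human fixture: 21 exons, 27 segments, 11-isoform catalog."""
    return _build_fixture(
        seed, "KIRREL3_human_synthetic", HUMAN_GENE_LENGTH, _HUMAN_EXONS,
        _HUMAN_CATALOG, tm_exon_id="16",
        ig_exon_ids=("5", "7", "9", "11", "13"),
        pdz_segment_id="21", signal_exon_id="3",
    )


def make_toy_model(seed: int, n_exons: int = 3, intron_len: int = 600,
                   exon_len: int = SEG_NT) -> GeneModel:
    """Small all-constitutive gene for unit tests and the discovery screen.

    One catalog isoform containing every exon from exon 2 on; exon 1 holds
    the primer site and the start codon (playing the role of the start exon).
    """
    assert exon_len % 3 == 0 and n_exons >= 2
    rng = np.random.default_rng(seed)
    rows = [("1", "constitutive", "extracellular", UTR_LEN + exon_len, "")]
    for i in range(2, n_exons + 1):
        rows.append((str(i), "constitutive",
                     "intracellular" if i == n_exons else "extracellular",
                     exon_len, ""))
    length = sum(r[3] for r in rows) + intron_len * (n_exons + 1)

    # reuse the fixture builder with a trivial catalog; exon "1" here is the
    # primer-bearing start exon, so rename ids afterwards is unnecessary
    exons = []
    pos = intron_len
    parts = []
    cursor = 0
    seqs = {}
    for exon_id, sclass, side, elen, _f in rows:
        if exon_id == "1":
            seqs[exon_id] = _random_dna(rng, UTR_LEN) + "ATG" + _coding(rng, exon_len - 3)
        elif exon_id == str(n_exons):
            seqs[exon_id] = _coding(rng, exon_len, final_stop=True)
        else:
            seqs[exon_id] = _coding(rng, exon_len)
        exons.append(Exon(exon_id, pos, pos + elen, sclass, side))
        parts.append(_random_dna(rng, pos - cursor))
        parts.append(seqs[exon_id])
        cursor = pos + elen
        pos = cursor + intron_len
    parts.append(_random_dna(rng, length - cursor))
    seq = "".join(parts)
    exon1 = exons[0]
    model = GeneModel(
        gene_id="toy_synthetic", length=length, sequence=seq, exons=tuple(exons),
        primer_site=(exon1.start + PRIMER_OFFSET, exon1.start + PRIMER_OFFSET + PRIMER_LEN),
        start_codon=exon1.start + UTR_LEN,
        tm_exon_id=str(n_exons), ig_exon_ids=frozenset(),
        pdz_segment_id=str(n_exons), signal_exon_id=None,
        catalog=(IsoformDef("T1", tuple(str(i) for i in range(1, n_exons + 1)), 100.0),),
    )
    model.validate()
    return model
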