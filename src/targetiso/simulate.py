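"""Simulation of barcoded full-length cDNA reads from a known isoform mixture.

Reads emulate a targeted long-read amplicon library: each target read is
``barcode + (start-exon sequence from the gene-specific primer) + spliced
segment sequences + polyA``, with independent per-base substitution,
insertion and deletion errors.  A configurable fraction of reads carries a
corrupted (heavily mutated or truncated) barcode, a fraction is off-target
background, and knockout-construct mode replaces target transcripts with
``5'-UTR + eGFP-marker`` reads.

The 16-nt barcode itself is exempt from the per-base error process: barcode
integrity is controlled exclusively by ``barcode_corrupt_frac``, so the
unassignable fraction is an interpretable parameter rather than a function
of the error rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .model import GeneModel, LongRead, isoform_sequence

__all__ = [
    "SimulationConfig",
    "BarcodeSet",
    "TruthRecord",
    "simulate_reads",
    "corrupt_barcode",
    "make_barcode_set",
    "default_barcode_set",
    "egfp_marker",
    "apply_errors",
    "reverse_complement",
]

BARCODE_LEN = 16
MIN_BARCODE_DIST = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Default error rates (2% substitution, 1% insertion, 1% deletion) are
    conventional for long-read consensus data; ``barcode_corrupt_frac``
    and ``background_frac`` default to the published library composition
    (14.2% unassignable barcodes; target reads 0.8% of the library would be
    impractical to simulate verbatim, so background defaults to 0 and is set
    per experiment).
    """

    isoform_weights: Mapping[str, float]
    n_reads: int
    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    barcode_corrupt_frac: float = 0.0
    background_frac: float = 0.0
    ko_mode: bool = False
    polya_len: int = 20
    revcomp_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        for name in ("sub_rate", "ins_rate", "del_rate", "barcode_corrupt_frac",
                     "background_frac", "revcomp_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not self.ko_mode:
            if not self.isoform_weights or sum(self.isoform_weights.values()) <= 0:
                raise ConfigError("isoform_weights must have positive total weight")
            if any(w < 0 for w in self.isoform_weights.values()):
                raise ConfigError("isoform weights must be non-negative")
        if self.polya_len < 0:
            raise ConfigError("polya_len must be >= 0")


@dataclass(frozen=True)
class BarcodeSet:
    """sample_id -> 16-nt barcode, pairwise Hamming distance >= 5."""

    barcodes: Mapping[str, str]

    def validate(self) -> None:
        for sid, bc in self.barcodes.items():
            if len(bc) != BARCODE_LEN or set(bc) - set("ACGT"):
                raise ConfigError(f"barcode for {sid!r} must be 16 nt of ACGT")
        for (s1, b1), (s2, b2) in itertools.combinations(self.barcodes.items(), 2):
            d = sum(a != b for a, b in zip(b1, b2))
            if d < MIN_BARCODE_DIST:
                raise ConfigError(
                    f"barcodes {s1!r}/{s2!r} at Hamming distance {d} < {MIN_BARCODE_DIST}"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.barcodes)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    sample_id: str
    true_isoform: str          # catalog label, or "background" / "ko"
    barcode_intact: bool
    strand: str = "+"          # emitted orientation


def make_barcode_set(sample_ids: Sequence[str], seed: int = 0) -> BarcodeSet:
    """Draw well-separated 16-nt barcodes for the given samples."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    while len(chosen) < len(sample_ids):
        cand = rng.choice(_BASES, size=BARCODE_LEN).tobytes().decode()
        if all(sum(a != b for a, b in zip(cand, bc)) >= MIN_BARCODE_DIST
               for bc in chosen):
            chosen.append(cand)
    bs = BarcodeSet(dict(zip(sample_ids, chosen)))
    bs.validate()
    return bs


def default_barcode_set() -> BarcodeSet:
    """The package's stock six-sample barcode set (four wild-type, two KO)."""
    return make_barcode_set(("WT1", "WT2", "WT3", "WT4", "KO1", "KO2"), seed=1805)


def egfp_marker() -> str:
    """The fixed 720-nt synthetic eGFP-like marker shipped with the package.

    A stand-in sequence (not the real eGFP ORF) used to mark
    knockout-construct transcripts; deterministic across sessions.
    """
    rng = np.random.default_rng(736_205)
    return rng.choice(_BASES, size=720).tobytes().decode()


def corrupt_barcode(barcode: str, mode: str, rng, barcode_set: BarcodeSet | None = None) -> str:
    """Damage a barcode beyond the demultiplexer's two-mismatch tolerance.

    ``mutate3`` substitutes three (escalating on the rare collision) random
    positions and guarantees Hamming distance >= 3 from every barcode in
    ``barcode_set`` (or from the source barcode when no set is given);
    ``truncate`` returns a proper prefix of length <= 8.
    """
    if len(barcode) != BARCODE_LEN:
        raise ConfigError("corrupt_barcode expects a 16-nt barcode")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if mode == "truncate":
        return barcode[: int(rng.integers(4, 9))]
    if mode != "mutate3":
        raise ConfigError(f"unknown corruption mode {mode!r}")
    references = list(barcode_set.barcodes.values()) if barcode_set else [barcode]
    n_mut = 3
    while True:
        pos = rng.choice(BARCODE_LEN, size=n_mut, replace=False)
        out = list(barcode)
        for p in pos:
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
        cand = "".join(out)
        if all(sum(a != b for a, b in zip(cand, ref)) >= 3 for ref in references):
            return cand
        n_mut = min(n_mut + 1, BARCODE_LEN)


def apply_errors(seq: str, rng: np.random.Generator, sub_rate: float,
                 ins_rate: float, del_rate: float) -> str:
    """Independent per-base substitution / insertion / deletion errors.

    An insertion places one random base immediately after the affected
    position.  Vectorized; a base experiences at most one event.
    """
    if not seq or (sub_rate == ins_rate == del_rate == 0.0):
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    u = rng.random(arr.size)
    del_mask = u < del_rate
    ins_mask = (u >= del_rate) & (u < del_rate + ins_rate)
    sub_mask = (u >= del_rate + ins_rate) & (u < del_rate + ins_rate + sub_rate)

    if sub_mask.any():
        # shift each substituted base by 1-3 positions in the ACGT alphabet
        idx = np.searchsorted(_BASES, arr[sub_mask])  # ACGT is sorted
        shift = rng.integers(1, 4, size=idx.size)
        arr[sub_mask] = _BASES[(idx + shift) % 4]

    counts = np.ones(arr.size, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2
    out = np.repeat(arr, counts)
    if ins_mask.any():
        ends = np.cumsum(counts)
        dup_pos = ends[ins_mask] - 1
        out[dup_pos] = rng.choice(_BASES, size=dup_pos.size)
    return out.tobytes().decode()


def _target_template(model: GeneModel, signature: Sequence[str], polya_len: int) -> str:
    """Error-free read body for one isoform: primer-trimmed transcript + polyA."""
    trimmed_start = model.primer_site[0] - model.exon(signature[0]).start
    body = isoform_sequence(model, signature)[trimmed_start:]
    return body + "A" * polya_len


def _ko_template(model: GeneModel, marker: str, polya_len: int) -> str:
    return model.utr_sequence + marker + "A" * polya_len


def simulate_reads(model: GeneModel, config: SimulationConfig,
                   barcodes: BarcodeSet) -> tuple[list[LongRead], list[TruthRecord]]:
    """Simulate a barcoded library; returns reads plus a ground-truth table.

    Sample assignment, category (target / background / KO), isoform choice,
    barcode corruption, errors and strand are all drawn from a single
    seeded generator, so identical configs give byte-identical output.
    """
    config.validate()
    barcodes.validate()
    rng = np.random.default_rng(config.seed)
    catalog = model.catalog_by_label()
    if not config.ko_mode:
        unknown = set(config.isoform_weights) - set(catalog)
        if unknown:
            raise ConfigError(f"isoform_weights refer to unknown isoforms: {sorted(unknown)}")

    labels = list(config.isoform_weights) if not config.ko_mode else []
    weights = None
    if labels:
        w = np.array([config.isoform_weights[l] for l in labels], dtype=float)
        weights = w / w.sum()
    templates = {l: _target_template(model, catalog[l].segments, config.polya_len)
                 for l in labels}
    ko_tpl = _ko_template(model, egfp_marker(), config.polya_len)
    bg_len = (int(np.median([len(t) for t in templates.values()]))
              if templates else len(ko_tpl))
    sample_ids = barcodes.sample_ids

    reads: list[LongRead] = []
    truth: list[TruthRecord] = []
    for i in range(config.n_reads):
        read_id = f"read{i:06d}"
        sample = sample_ids[int(rng.integers(len(sample_ids)))]
        if rng.random() < config.background_frac:
            category = "background"
            body = rng.choice(_BASES, size=bg_len).tobytes().decode()
        elif config.ko_mode:
            category = "ko"
            body = ko_tpl
        else:
            category = str(rng.choice(labels, p=weights))
            body = templates[category]
        body = apply_errors(body, rng, config.sub_rate, config.ins_rate, config.del_rate)

        barcode = barcodes.barcodes[sample]
        intact = True
        if rng.random() < config.barcode_corrupt_frac:
            intact = False
            mode = "mutate3" if rng.random() < 0.5 else "truncate"
            barcode = corrupt_barcode(barcode, mode, rng, barcodes)

        seq = barcode + body
        strand = "+"
        if rng.random() < config.revcomp_frac:
            seq = reverse_complement(seq)
            strand = "-"
        reads.append(LongRead(read_id, seq, quality="I" * len(seq)))
        truth.append(TruthRecord(read_id, sample, category, intact, strand))
    return reads, truth


def simulate_per_isoform(model: GeneModel, barcodes: BarcodeSet,
                         n_per_isoform: int, seed: int,
                         **config_overrides) -> tuple[list[LongRead], list[TruthRecord]]:
    """Fixed per-isoform read counts: one simulation per catalog isoform.

    Read ids are prefixed with the isoform label so they stay unique across
    the combined library.
    """
    import dataclasses

    reads: list[LongRead] = []
    truth: list[TruthRecord] = []
    for i, iso in enumerate(model.catalog):
        cfg = SimulationConfig(isoform_weights={iso.label: 1.0},
                               n_reads=n_per_isoform,
                               seed=(seed + 7919 * i) % 2**31, **config_overrides)
        rs, ts = simulate_reads(model, cfg, barcodes)
        for r, t in zip(rs, ts):
            rid = f"{iso.label}_{r.read_id}"
            reads.append(dataclasses.replace(r, read_id=rid))
            truth.append(dataclasses.replace(t, read_id=rid))
    return reads, truth
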