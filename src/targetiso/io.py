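"""Standard-format I/O.

* reads: FASTA/FASTQ via Biopython;
* gene model: GFF3 (exons, a/b parts as child features) + a segment TSV +
  the gene sequence as FASTA + the isoform catalog as TSV;
* barcodes / ground truth / report tables: TSV (tab-separated, header row,
  UTF-8, no quoting);
* simulation config: YAML key-value file mirroring
  :class:`~targetiso.simulate.SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .model import Exon, GeneModel, IsoformDef, LongRead
from .simulate import BarcodeSet, SimulationConfig, TruthRecord

__all__ = [
    "read_reads", "write_fastq", "write_fasta",
    "write_gene_model", "read_gene_model",
    "write_barcodes", "read_barcodes",
    "write_truth", "read_truth",
    "write_config", "read_config",
]

_QOFF = 33


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _to_record(read: LongRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description=read.description)
    if read.quality is not None:
        rec.letter_annotations["phred_quality"] = [ord(c) - _QOFF for c in read.quality]
    return rec


def write_fastq(reads: Iterable[LongRead], path: str | os.PathLike) -> None:
    recs = []
    for r in reads:
        if r.quality is None:
            r = dataclasses.replace(r, quality="I" * len(r.sequence))
        recs.append(_to_record(r))
    SeqIO.write(recs, str(path), "fastq")


def write_fasta(reads: Iterable[LongRead], path: str | os.PathLike) -> None:
    SeqIO.write((SeqRecord(Seq(r.sequence), id=r.read_id, description=r.description)
                 for r in reads), str(path), "fasta")


def read_reads(path: str | os.PathLike) -> list[LongRead]:
    """Read FASTA or FASTQ (by extension) into LongRead records."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    try:
        out = []
        for rec in SeqIO.parse(str(path), fmt):
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(chr(q + _QOFF) for q in rec.letter_annotations["phred_quality"])
            out.append(LongRead(rec.id, str(rec.seq).upper(), qual, rec.description))
        return out
    except ValueError as exc:
        raise ParseError(f"malformed {fmt} file: {exc}", path=str(path)) from exc


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

def _gff_attrs(**kw) -> str:
    return ";".join(f"{k}={v}" for k, v in kw.items() if v not in (None, ""))


def write_gene_model(model: GeneModel, outdir: str | os.PathLike) -> None:
    """Serialize a model to ``<outdir>/{gene.gff3,segments.tsv,gene.fa,catalog.tsv}``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = model.gene_id
    lines = ["##gff-version 3", f"##sequence-region {gid} 1 {model.length}"]
    lines.append("\t".join([
        gid, "targetiso", "gene", "1", str(model.length), ".", "+", ".",
        _gff_attrs(ID=gid,
                   primer_start=model.primer_site[0], primer_end=model.primer_site[1],
                   start_codon=model.start_codon, tm_exon=model.tm_exon_id,
                   pdz_segment=model.pdz_segment_id,
                   ig_exons=",".join(sorted(model.ig_exon_ids, key=_natkey)),
                   signal_exon=model.signal_exon_id or "")]))
    for ex in model.exons:
        eid = f"exon_{ex.exon_id}"
        lines.append("\t".join([
            gid, "targetiso", "exon", str(ex.start + 1), str(ex.end), ".", "+", ".",
            _gff_attrs(ID=eid, Parent=gid, exon_id=ex.exon_id,
                       splice_class=ex.splice_class, protein_side=ex.protein_side,
                       signal_peptide=int(ex.has_signal_peptide),
                       b_introduces_stop=int(ex.b_introduces_stop))]))
        if ex.splice_class == "extendable":
            for part, iv in (("a", ex.a_part), ("b", ex.b_part)):
                lines.append("\t".join([
                    gid, "targetiso", "exon_part", str(iv[0] + 1), str(iv[1]),
                    ".", "+", ".",
                    _gff_attrs(ID=f"{eid}{part}", Parent=eid, part=part)]))
    (outdir / "gene.gff3").write_text("\n".join(lines) + "\n")

    seg_rows = [{"segment_id": s.segment_id, "start": s.start, "end": s.end,
                 "introduces_stop": int(s.introduces_stop),
                 "terminal_if_present": int(s.terminal_if_present),
                 "protein_side": s.protein_side}
                for s in model.segments]
    pd.DataFrame(seg_rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)

    SeqIO.write([SeqRecord(Seq(model.sequence), id=gid, description="")],
                str(outdir / "gene.fa"), "fasta")

    cat_rows = [{"label": iso.label, "segments": "+".join(iso.segments),
                 "freq_label": "" if iso.freq_label is None else iso.freq_label}
                for iso in model.catalog]
    pd.DataFrame(cat_rows, columns=["label", "segments", "freq_label"]).to_csv(
        outdir / "catalog.tsv", sep="\t", index=False)


def _natkey(s: str):
    return (len(s), s)


def read_gene_model(indir: str | os.PathLike) -> GeneModel:
    import gffutils

    indir = Path(indir)
    gff_path = indir / "gene.gff3"
    try:
        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="error")
    except Exception as exc:
        raise ParseError(f"malformed GFF3: {exc}", path=str(gff_path)) from exc

    def attr1(feature, key, default=None):
        # GFF3 attribute values are comma-separated lists; rejoin multi-values
        vals = feature.attributes.get(key, [])
        return ",".join(vals) if vals else default

    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise ParseError(f"expected exactly one gene feature, found {len(genes)}",
                         str(gff_path))
    gene = genes[0]
    exon_rows: dict[str, dict] = {}
    parts: dict[str, dict[str, tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        exon_rows[attr1(feat, "ID")] = {
            "attrs": {k: attr1(feat, k) for k in feat.attributes},
            "start": feat.start - 1, "end": feat.end}
    for feat in db.features_of_type("exon_part"):
        parts.setdefault(attr1(feat, "Parent"), {})[attr1(feat, "part")] = (
            feat.start - 1, feat.end)
    gat = {k: attr1(gene, k) for k in gene.attributes}
    gcols = (gene.seqid, None, None, None, gene.end)

    recs = list(SeqIO.parse(str(indir / "gene.fa"), "fasta"))
    if len(recs) != 1:
        raise ParseError("gene.fa must contain exactly one record", str(indir / "gene.fa"))
    sequence = str(recs[0].seq).upper()

    exons = []
    for eid, row in exon_rows.items():
        a = row["attrs"]
        ab = parts.get(eid, {})
        exons.append(Exon(
            exon_id=a["exon_id"], start=row["start"], end=row["end"],
            splice_class=a["splice_class"], protein_side=a["protein_side"],
            a_part=ab.get("a"), b_part=ab.get("b"),
            has_signal_peptide=a.get("signal_peptide") == "1",
            b_introduces_stop=a.get("b_introduces_stop") == "1"))
    exons.sort(key=lambda e: e.start)

    cat_path = indir / "catalog.tsv"
    catalog: tuple[IsoformDef, ...] = ()
    if cat_path.exists():
        df = pd.read_csv(cat_path, sep="\t", dtype={"label": str})
        catalog = tuple(
            IsoformDef(str(r.label), tuple(r.segments.split("+")),
                       None if pd.isna(r.freq_label) else float(r.freq_label))
            for r in df.itertuples())

    model = GeneModel(
        gene_id=gcols[0], length=int(gcols[4]), sequence=sequence,
        exons=tuple(exons),
        primer_site=(int(gat["primer_start"]), int(gat["primer_end"])),
        start_codon=int(gat["start_codon"]),
        tm_exon_id=gat["tm_exon"], pdz_segment_id=gat["pdz_segment"],
        ig_exon_ids=frozenset(x for x in (gat.get("ig_exons") or "").split(",") if x),
        signal_exon_id=gat.get("signal_exon") or None,
        catalog=catalog)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# barcodes, truth, config
# ---------------------------------------------------------------------------

def write_barcodes(barcodes: BarcodeSet, path: str | os.PathLike) -> None:
    pd.DataFrame([{"sample_id": s, "barcode": b} for s, b in barcodes.barcodes.items()]
                 ).to_csv(path, sep="\t", index=False)


def read_barcodes(path: str | os.PathLike) -> BarcodeSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
        bs = BarcodeSet({r.sample_id: r.barcode for r in df.itertuples()})
    except Exception as exc:
        raise ParseError(f"malformed barcode TSV: {exc}", path=str(path)) from exc
    bs.validate()
    return bs


def write_truth(truth: Iterable[TruthRecord], path: str | os.PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "true_isoform": str})


def write_config(config: SimulationConfig, path: str | os.PathLike) -> None:
    data = dataclasses.asdict(config)
    data["isoform_weights"] = dict(config.isoform_weights)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config(path: str | os.PathLike) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        cfg = SimulationConfig(**data)
    except TypeError as exc:
        raise ParseError(f"bad simulation config: {exc}", path=str(path)) from exc
    cfg.validate()
    return cfg
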