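# targetiso

Targeted long-read isoform analysis for a single gene of interest.

Synaptic cell-adhesion genes such as Kirrel3 are expressed too sparsely for
their splice isoforms to be visible in bulk short-read data: the transcript
may be well under 0.001% of a brain mRNA pool, and short reads cannot link
distant exons into one transcript. A practical answer is a *targeted*
long-read amplicon library: amplify full-length cDNA with a gene-specific
forward primer anchored in the start exon, barcode each sample, sequence,
and then ask of every read *which alternatively spliced segments does it
contain?* `targetiso` implements that analysis end to end, for
transcriptomics researchers who want a tested, reusable version of the
approach, together with a read simulator that makes every stage testable
against known ground truth.

## The method

The gene model decomposes the locus into **segments**: constitutive and
skippable exons contribute their full sequence; an exon with two
alternative 3′ splice sites contributes a short form *a* and a 3′ extension
*b* (several *b* extensions carry premature stop codons and act as
alternative transcript ends). For the encoded mouse gene this yields 29
segments from 22 exons; for the human gene, 27 segments from 21 exons.

For a read *r* and segment *s*, presence is decided by bounded approximate
matching:

    present(s, r)  ⇔  min over substrings w of r (either strand) of
                      d_edit(s, w)  ≤  ⌊0.4 · |s|⌋

with edit distance (substitutions + indels) computed in infix mode by
edlib. Demultiplexing assigns a read to a sample when a unique 16-nt
barcode matches within ≤ 2 Hamming mismatches near either read end. A read
is **full-length** when it contains the start-exon primer region and ends
in a polyA tail; the ordered set of segments detected in a full-length read
is its **signature**. Signatures matching the isoform catalog inherit its
label; consistent new signatures are reported as novel; reads violating the
splicing grammar (material downstream of a stop-bearing terminal segment,
or a *b* extension without its *a* form) are excluded. Isoform frequencies
are percentages of full-length consistent reads, and each isoform is
classified from where translation stops relative to the
transmembrane-encoding exon: **secreted** (stop upstream of it), **TM_short**
(stop in the short-tail extension downstream of it) or **TM_long_PDZ** (the
PDZ-encoding terminal exon included). A small companion module maps exon
presence/absence across species onto a rooted tree, assigning each exon the
most recent common ancestor of its carriers (single-gain assumption).

A whole-gene discovery screen supports finding unannotated exons: the locus
(introns included) is tiled into 155-bp fragments and each fragment is
screened against the full-length reads; fragments with read support outside
annotated exons are flagged.

## Worked example

```python
import targetiso as ti

model = ti.make_mouse_fixture(1)          # 22 exons, 29 segments, 19 isoforms
barcodes = ti.default_barcode_set()

# simulate a library at the published isoform mix, with barcode dropout
weights = {iso.label: iso.freq_label for iso in model.catalog}
cfg = ti.SimulationConfig(isoform_weights=weights, n_reads=3000,
                          barcode_corrupt_frac=0.142, seed=42)
reads, truth = ti.simulate_reads(model, cfg, barcodes)

result = ti.run_pipeline(reads, model, barcodes)
c = result.summary.counts
print(c["total_reads"], c["assigned"], c["assigned_pct"])
print(result.isoform_table.table.head(4)[["label", "count", "frequency_pct"]])
print(ti.cumulative_segment_frequency(result.isoform_table, "22", model))
print(result.classes)
```

prints

```
3000 2593 86.4
  label  count  frequency_pct
0     A    633      24.411878
1     B    512      19.745469
2     C    360      13.883533
3     F    292      11.261088
```

then `94.48515233320478` and

```
         class  n_reads  frequency_pct
0  TM_long_PDZ     2450      94.485152
1     TM_short       29       1.118396
2     secreted      114       4.396452
```

— 86.4% of reads demultiplexed (14.2% of barcodes were corrupted by
configuration), per-isoform frequency estimates tracking the simulated
mixture, ~95% of transcripts carrying the PDZ-encoding terminal exon, and
the three C-terminal protein classes partitioning the full-length reads.

The same stages are available as a CLI (`targetiso simulate | demux |
screen | call | classify | phylo | all`); every threshold is a flag with
the defaults above.

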