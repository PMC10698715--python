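# Methods

## Gene model and segments

A locus is modeled as an ordered list of non-overlapping exons on a single
gene coordinate system (0-based, half-open). Three splice classes are
distinguished: *constitutive* exons, *skippable* exons (cassette exons), and
*extendable* exons whose two alternative 3′ splice sites produce a short
form (*a*) and a 3′ extension (*b*, starting exactly where *a* ends). The
screening unit is the **segment**: the full exon for
constitutive/skippable exons, plus one segment each for the *a* part and
the *b* extension of extendable exons, in genomic order. The segment count
is therefore `#exons + #b-extensions` for every well-formed model.

Stop-bearing segments (a *b* extension carrying a premature stop codon, or
a stand-alone stop-bearing cassette exon) are flagged
`terminal_if_present`: when spliced in, the transcript ends there, so no
gene segment is expected downstream. Protein-side annotations
(extracellular / transmembrane / intracellular / UTR), the identities of
the Ig-domain-encoding exons, the signal-peptide exon, the
transmembrane-encoding exon and the PDZ-encoding terminal segment are part
of the model, not sequence predictions.

Two fixtures encode the published mouse and human Kirrel3 topologies with
synthetic sequences: mouse — 22 exons, extendable exons 8, 9, 11, 13, 17,
19, 20, stop-bearing extensions {8b, 9b, 11b, 13b, 17b, 20b}, stand-alone
stop exon 10, skippable exons {6, 18, 22}, predicted exons 3–5 present in
the model but absent from the catalog, and a 19-isoform catalog (13
transmembrane, 6 secreted); human — 21 exons, 27 segments, an 11-isoform
catalog (8 transmembrane, 3 secreted) including a great-ape-specific
intracellular cassette exon. Per-isoform frequency labels stored with the
catalogs sum to 100% with the aggregate composition 95% (PDZ-terminal) /
~1% (short-tailed) / 4% (secreted); they parameterize simulations and are
never produced as results.

### Why fixture segments are 210 nt

The presence call is `min_w d_edit(segment, w) ≤ ⌊0.4·L⌋` over substrings
`w` of the read. Against *unrelated* sequence this minimum concentrates
near 0.45–0.46·L for random DNA, so the margin over the 0.4·L acceptance
bound grows (and the false-match probability decays roughly exponentially)
with segment length. Measured with edlib on random sequence, the per-pair
false-match probability at the 40% bound is ≈1 for 30-nt segments, ≈3×10⁻²
at 90 nt, ≈5×10⁻⁴ at 150 nt and <3×10⁻⁵ at 210 nt (30,000 trials,
including 2%/1%/1% read errors). Fixture coding segments are therefore 70
codons (210 nt) — long enough that a library of thousands of reads
screened against ~30 segments produces essentially no chance detections,
while remaining in the size range of real exons. Two further guards are
enforced at build time by rejection-resampling individual segments:
pairwise global edit distance between segments ≥ 50% of the shorter, and
infix distance of every segment against every catalog transcript *not*
containing it > 43% of the segment length. Construction stays
deterministic per seed.

Coding segments are whole numbers of sense codons, so reading frame is
conserved across every catalog combination; stop codons occur only where
the topology places them (codon 6 of short-tail extensions, codon 3 of
stand-alone stop exons and secreted-form extensions, the final codon of
the PDZ-terminal exon). The start exon carries a 70-nt 5′ UTR whose first
50 nt are the gene-specific primer region, followed by the ATG.

## Read simulation

A target read is `barcode (16 nt) + transcript from the primer + polyA`
(default 20 nt), with independent per-base substitution / insertion /
deletion errors (defaults 2% / 1% / 1%, conventional for long-read
consensus data; the generator makes no homopolymer or quality-score
claims). Half of the reads are emitted reverse-complemented so strand
handling is always exercised. Background reads are random sequences
length-matched to the target templates — they emulate off-target library
content without modeling a transcriptome. Knockout-construct mode emits
`barcode + start-exon 5′ UTR + 720-nt synthetic eGFP-like marker + polyA`.

Barcode integrity is controlled *only* by `barcode_corrupt_frac`
(heavy mutation at ≥3 positions from every barcode in the set, or
truncation to ≤8 nt); the per-base error process does not touch the
barcode. Rationale: at 1%/1% indel rates ~27% of reads would otherwise
acquire an indel inside the 16-mer, which the Hamming-window demultiplexer
cannot absorb, and the unassignable fraction would no longer converge to
the configured parameter. With this choice the assigned fraction is the
interpretable quantity `1 − barcode_corrupt_frac` (up to rare chance
matches), matching how the published figure of 85.8% assigned / 14.2%
excluded is used as a study condition.

What the simulator does *not* emulate: chimeric reads, PCR duplicates,
realistic quality strings, homopolymer-biased errors, or a real off-target
transcriptome. Passing tests therefore demonstrate the correctness and
calibration of the analysis under a clean generative model, not robustness
to every artifact of real libraries.

## Demultiplexing

The metric is Hamming distance of each 16-nt barcode over a sliding window
in the first and last 50 nt of the read, both strands (barcodes are
primer-appended, so searching whole reads would only inflate chance
matches). A read is assigned when a unique barcode achieves the minimum
distance and it is ≤ 2; ties are always unassigned. Assignment depends
only on the argmin structure, so raising the mismatch budget can only add
assignments, never change one.

## Segment screening and the full-length filter

`detect_segment` computes the infix (semi-global) edit distance with edlib
on both strands and applies the closed bound `⌊max_mismatch_frac · L⌋`
(default 0.4). Edit distance rather than Hamming is used because long
reads contain indels; an independent dynamic-programming oracle pins the
semantics in the tests. For per-read screening the read is first oriented
by its primer-region match (falling back to the polyA side), so match
positions of present segments are comparable in genomic order.

A read is **full-length** when the primer region is detected at the same
threshold and the read terminus carries a polyA tail, defined as a ≥10-nt
window with ≥90% adenine within the last 30 nt (the tail definition is a
package convention; only "has a polyA tail" is inherited from the
protocol). Full-length status gates every frequency denominator. Reads in
which no segment is detected at all are not gene transcripts and are
excluded from calling.

The discovery screen tiles the entire locus (introns included) into
155-bp fragments (`ceil(length/window)` fragments; the last may be short)
and counts, per fragment, the full-length reads in which it is detected at
the 40% bound. Fragments outside annotated exons with support in ≥5
full-length reads *and* ≥1% of them are flagged as candidate novel exonic
regions; both thresholds are parameters — the support rule is a package
choice, deliberately permissive, since any flagged tile is expected to be
inspected and incorporated into a revised model.

The knockout check requires the start-exon 5′ UTR region and the marker,
in that order, each at the 40% bound. Reads flagged as knockout constructs
are excluded from isoform calling.

## Isoform calling and frequencies

A read's signature is the ordered set of detected segments. Consistency
requires (i) nothing downstream of a stop-bearing terminal segment and
(ii) no *b* extension without its *a* form; violating reads are flagged
and excluded rather than reinterpreted. Exact catalog matches inherit the
catalog label; other consistent signatures receive a stable
`NOVEL:<sha1-prefix>` label, so identical signatures get identical labels
across runs. Every called isoform is reported regardless of read support
(`min_support` defaults to 1 and is a CLI flag), because biologically
validated isoforms occur at well under 1% frequency.

`frequency(i) = 100 · count(i) / N` with `N` the number of full-length,
consistent, non-knockout calls; zero eligible reads yield an empty table
with an explicit zero denominator. Cumulative segment frequency sums the
frequencies of called isoforms whose signature contains the segment.

## Protein classification

Classification is structural, from the signature's terminal segment
relative to the transmembrane exon: a stop-bearing terminal segment
upstream of it ⇒ *secreted*; downstream of it ⇒ *TM_short*; otherwise the
PDZ-terminal segment must be present ⇒ *TM_long_PDZ*; anything else is a
surfaced classification error, never a guess. The test-suite checks this
rule against the position of the first in-frame stop obtained by actual
translation of each catalog isoform. Ig-domain counts are the number of
Ig-annotated exons in the signature; signal-peptide status is the
annotation flag of the signal exon (sequence-based signal-peptide
prediction is out of scope).

## Exon origins on a species tree

Under a single-gain (Dollo-style) assumption the origin branch of an exon
is the most recent common ancestor of all species carrying it; losses
inside the carrier clade are permitted and ignored, and `NA` entries are
skipped. Dendropy supplies tree parsing and MRCA computation; an
exhaustive scan over all internal nodes serves as the oracle in tests. A
toy chordate fixture (chordates ⊃ amniotes ⊃ placental mammals ⊃
Hominidae, 15 tips with labeled internal nodes) reproduces the published
origin assignments qualitatively. Homology search itself is an input, not
a feature.

## Numerical and design choices

* Thresholds: barcode ≤2 mismatches; segment bound `⌊0.4·L⌋` (floor makes
  the boundary exact and testable); tile window 155 bp; polyA ≥9 A in a
  10-nt window over the last 30 nt. All are parameters with these
  defaults.
* Tiling is non-overlapping with the final partial window retained, which
  reproduces the 3772-fragment count for the 584,513-bp human locus. The
  corresponding published mouse fragment count is not derivable from any
  simple tiling of 550,823 bp and is deliberately not reproduced.
* Ambiguity always resolves to "no call": demux ties are unassigned;
  inconsistent signatures are excluded; unclassifiable signatures raise.
* Determinism: every stochastic component takes a single integer seed
  (numpy `default_rng`); identical seeds give byte-identical FASTQ and
  report files. Wall-clock timings are kept out of written reports so
  golden runs compare byte-for-byte.
* Problem sizes in the shipped tests and the acceptance script (hundreds
  of reads per check; 2,000–5,000 for calibration and mixture recovery;
  20 seeds for the estimator-calibration property) were chosen as the
  smallest sizes at which the binomial confidence intervals are clearly
  inside the asserted tolerances.

## Known limitations

* The 40% bound is only meaningful when segments are long enough and
  mutually distinguishable; the fixture enforces this, but applying the
  screen to a real gene with very short or repetitive exons would require
  either longer anchors or a lower bound.
* Error rates are treated as independent and per-base; no attempt is made
  to fit a platform-specific profile.
* Single-gene models only; no multi-gene batching, no alignment (BAM)
  output, and no de novo open-reading-frame discovery — translation always
  starts at the model's annotated start codon.
* The origin-branch operation assumes a single gain; recurrent gains or
  horizontal events would be misassigned by construction.
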