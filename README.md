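# duplexindel

Somatic small insertion/deletion (indel) calling from Tn5
transposase-based duplex sequencing data, at single-molecule resolution.

## The problem

Somatic mutations in non-clonal cell populations — post-mitotic neurons,
microbulk input, polyploid tissues — occur at allele fractions far below
what bulk variant callers can separate from sequencing error. Duplex
sequencing solves this by reading *both strands* of each original DNA
molecule independently: a true mutation is present on both strands,
while most artifacts (polymerase errors, single-strand DNA damage) are
not. In Tn5-based protocols the transposase fragments the genome and
tags both fragment ends with barcodes; the barcode pair identifies the
source molecule and the adaptor orientation identifies the strand.

`duplexindel` implements the full indel-calling path for such data:

1. **Preprocessing** — terminal barcode extraction against a reference
   barcode list (Hamming matching), adapter trimming, and merging of
   overlapping read-pair ends (with an ambiguity detector for
   tandem-repeat/microhomology read ends that can produce false merges).
2. **Molecule grouping** — aligned reads are pooled by barcode pair and
   Tn5 cut sites (fragment endpoints); reads from the two strands of one
   molecule present the barcodes in opposite order and are recovered by
   orientation. Two molecules sharing a barcode pair (a *barcode
   collision*) are detected by inconsistent cut sites.
3. **Duplex-consensus calling** — per-molecule, strand-aware pileup of
   left-normalized indel alleles under an `aXsY` threshold: at least
   `X` alt-supporting reads in total (`-a`) and at least `Y` on *each*
   strand (`-s`). The default is `a4s2`. Candidates reaching `a` on one
   strand only are emitted to a separate single-strand track — the
   signature of DNA damage and other single-strand artifacts.
4. **Somatic filtering** — germline removal against matched bulk WGS,
   merge-confound and adjacent-germline filters, cut-site consistency
   (barcode collisions), population allele frequency (gnomAD-style
   table, ≥ 1% by default), high-confidence genome mask, and
   sex-chromosome exclusion. Every filter is independently switchable.
5. **Benchmarking** — COSMIC ID83 83-channel indel spectra, cosine
   similarity against reference spectra, bootstrap confidence intervals
   with user-supplied negative-control spectra, and molecule-level
   down-sampling.

A fully ground-truthed synthetic data generator (`duplexindel.simulate`)
emulates the entire experiment — reference with planted repeat tracts,
barcoded duplex molecules, germline/somatic indels, single-strand
artifacts, barcode collisions, mis-merges, common variants — so every
stage is testable without external data or an aligner.

## Worked example

Simulate a small duplex experiment and call somatic indels:

```sh
duplex-indel simulate --out sim --seed 11 --n-molecules 300 --n-somatic 60
duplex-indel run --bam sim/duplex.bam --reference sim/reference.fa \
    --bulk-tsv sim/bulk_pileup.tsv --af-tsv sim/population_af.tsv \
    --out calls -a 4 -s 2
```

The run report printed by the second command (also written to
`calls/report.json`):

```json
{
 "candidates_double": 73,
 "candidates_single": 0,
 "filtered": {"germline": 13, "common_variant": 0, "cutsite_inconsistent": 0,
              "low_bulk_depth": 0, "masked": 0, "merge_confound": 0,
              "near_germline": 0},
 "multi_label": 0,
 "n_molecules": 305,
 "n_reads": 1542,
 "pass": 60,
 "sites": 71,
 "threshold": "a4s2"
}
```

Reading: 1542 reads grouped into 305 molecules yielded 73 double-strand
consensus candidates at `a4s2`; 13 were also present in the bulk pileup
and removed as germline; the 60 PASS calls are exactly the 60 somatic
indels the simulator planted. `calls/somatic.vcf` holds one record per
site, e.g.

```
chr1  2688  .  T  TTA  .  germline  NT=5;NP=2;NM=3;SD=DOUBLE;MOLN=1;MOL=c44168de486e
```

where `NT`/`NP`/`NM` are total and per-strand alt read counts, `SD` the
strandedness, and `MOLN` the number of supporting molecules. Filtered
records are retained with their FILTER labels; single-strand calls go to
`calls/single_strand.vcf` and never PASS.

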