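# Methods

## Calling model

A duplex molecule is one original double-stranded DNA fragment, keyed by
`(chrom, unordered barcode pair, fragment start, fragment end)`. The
fragment endpoints are the Tn5 cut sites; because both strands of one
molecule share them, they double as a collision detector: reads with the
same barcode pair but endpoints differing beyond `cutsite_tolerance`
(default 0 bp, configurable to 2 bp for noisy ends) are split into
separate molecules, all flagged `cutsite_consistent = False`. Strand is
assigned from alignment orientation: the read whose first barcode was
sequenced at the leftmost fragment coordinate is the plus-strand read;
the complementary strand presents the barcodes in reverse order and
aligns reversed.

Calling is deliberately threshold-based, not likelihood-based: within
one molecule, an indel allele (taken from the alignment CIGAR as-is, no
local realignment, then left-normalized against the reference) is a
candidate when at least `a` reads support it in total, and a
double-strand (consensus) call when each strand contributes at least
`s` supporting reads. Defaults `a=4, s=2`. Candidates reaching `a` on
one strand only are labelled single-stranded and emitted on a separate
track; they are compatible with single-strand DNA damage or library
artifacts and never PASS. Each molecule contributes at most one
candidate per allele; multiple molecules at one site are collapsed at
VCF emission with the per-molecule tally in `INFO/MOLN`.

Left-normalization uses the standard VCF shift-left algorithm (trim
shared trailing bases, re-extend with the preceding reference base,
reduce to a single shared anchor). It is what makes germline and
population-AF lookups exact, since the same physical event can be
reported at different anchors inside repeat tracts.

### Read-quality gates

* mapping quality ≥ 30 before molecule grouping (the threshold is a
  declared default — low-quality read removal is required but the exact
  cutoff is an open choice — and is configurable);
* indel support requires base quality ≥ 20 on the anchor base and the
  first base after the event;
* secondary/supplementary/unmapped records are discarded.

## Filters

Filters are commutative label-writers: each adds its own label to a
candidate's filter set, so the outcome is independent of application
order, and disabling any filter can only grow the PASS set.

| label | rule | default knobs |
|---|---|---|
| `germline` | ≥ 1 alt read for the identical normalized allele in matched bulk | — |
| `low_bulk_depth` | bulk depth < 10 at the site (cannot be vetted; removed conservatively) | `germline_min_bulk_depth=10` |
| `near_germline` | a *distinct* bulk germline indel (bulk alt ≥ 2 or VAF ≥ 0.2) within 10 bp of the anchor | `adjacency_window=10` |
| `cutsite_inconsistent` | supporting molecule flagged as barcode collision | — |
| `common_variant` | population AF ≥ 0.01 in the supplied table | `af_cutoff=0.01` |
| `merge_confound` | see below | — |
| `masked` | outside the supplied high-confidence BED (applied at candidate generation) | — |

The single-alt-read germline rule is maximally conservative on purpose:
with 30× bulk, a heterozygous germline indel is essentially never
alt-free, while a true somatic event in a non-clonal sample is
essentially never present in bulk. The adjacency window and the
germline-set definition (alt ≥ 2 or VAF ≥ 0.2 rather than ≥ 1 read)
keep single-read bulk noise from defining "difficult regions".

**Merge confound.** Merging overlapping read-pair ends improves base
quality but can fabricate indels when the two ends share sequence
without truly overlapping (tandem repeats, microhomology). The merger
therefore records an ambiguity bit: a merge is ambiguous when a second
candidate offset — itself passing the mismatch-rate gate — scores at
least 90% of the best offset's match count. A candidate is labelled
`merge_confound` when every supporting read places the event inside its
merged-overlap interval and any of those merges was ambiguous, or when
the event's repeat tract (unit ≤ 6 bp, tract ≥ 12 bp) spans a merge
boundary. Missing merge metadata yields `not_evaluable` and the
candidate passes with a warning rather than being silently dropped.

## Spectra and benchmarking

Indel spectra use the 83-channel COSMIC ID83 classification: 1-bp
indels by the pyrimidine identity of the indel base and homopolymer
run length; ≥ 2-bp indels by the number of tandem copies of the indel
sequence in the flanking reference; multi-base deletions with no tandem
copy but a shared flank by microhomology length. Classification
operates on left-normalized alleles with ± 50 bp of context and is
total: every simple indel maps to exactly one channel.

The benchmark statistic is the cosine similarity between a recovered
and a reference spectrum. Spectrum-level (rather than variant-level)
comparison is the right granularity for single-molecule callers, which
detect private mutations absent from any bulk-derived truth set.

**Bootstrap.** Calls (channel labels) are resampled with replacement
`B=1000` times; similarities to the reference and to each
negative-control spectrum are summarised by a *recentred* percentile
95% interval: the raw 2.5/97.5 percentiles are shifted so that the
interval is centred on the observed similarity (clipped at 1.0). The
recentring matters: resampling doubles the multinomial noise in the
spectrum, biasing resampled similarities systematically below the
observed value, so a raw percentile interval routinely excludes its own
point estimate. The separation criterion — observed similarity to the
reference above the control interval's upper bound — is slightly more
conservative under recentring. BCa was considered and rejected as
unnecessary machinery at these call counts.

**Down-sampling** operates at molecule level, retaining each molecule
independently with probability `fraction`; read-level thinning would
break duplex families and conflate depth with consensus loss.

## The synthetic data generator

`duplexindel.simulate` emulates the full experiment and is the test
bed for every pipeline stage. Defaults describe one study condition:

* reference: 100 kb random autosome (uniform base composition, GC ≈
  0.5) with planted homopolymers (8–12 bp) and tandem repeats (unit
  2–6 bp, ≥ 12 bp) every 5 kb, plus a 12 kb `chrX` contig to exercise
  sex-chromosome exclusion;
* 1000 molecules, fragment length ~N(240, 25) clipped to [180, 280],
  2–3 reads per strand, 64 barcodes of length 8 with pairwise Hamming
  distance ≥ 3 (unambiguous matching at one mismatch); distinct
  molecules receive distinct barcode pairs unless a collision is
  injected, so collision truth is exact;
* 30 germline indels (VAF 0.5 or 1.0; bulk pileup table carries the
  matching evidence at 30×), 200 somatic indels of 1–3 bp, each private
  to both strands of one molecule; planted events keep ≥ 20 bp apart
  and ≥ 40 bp from planted repeat tracts so that truth labels are
  unambiguous, and every retained germline site is guaranteed at least
  one carrier molecule (sites no molecule covers are dropped);
* substitution sequencing errors at 0.001/bp, never inside inserted
  bases (indel truth stays exact; indel sequencing errors are off by
  default);
* artifact classes, each independently switchable and recorded in the
  truth set: single-strand artifacts (placed on one strand with a
  4–5-read family so they register at `a4` and exercise the
  single-strand track), barcode collisions (pair reuse at a distant
  locus), mis-merges (a false one-unit deletion inside an ambiguous
  merged overlap at a planted repeat), and common variants (planted
  alleles listed at AF 0.05 in the population table, plus sub-cutoff
  decoy rows at AF 0.005 that must *not* filter);
* a `mixture_fraction` parameter confines somatic events to a
  subpopulation of molecules, emulating tumor-into-normal dilution
  series.

The generator emits both raw barcoded FASTQ (for the preprocessor) and
pre-aligned tagged BAM records computed from the known placement, so
the caller is testable without an aligner; the two in-memory and
on-disk paths produce identical candidates. What the simulation does
*not* model: Tn5 insertion-site sequence bias, PCR family-size
distributions beyond the configurable reads-per-strand range, mapping
error, or real genomic repeat structure at scale. Passing round-trip
tests therefore demonstrate the correctness of the calling and
filtering logic under the stated error model, not calling performance
on real genomes.

For spectrum benchmarks, `sample_alleles_from_spectrum` draws channels
from a given 83-channel distribution and builds an explicit sequence
context realizing each draw (run lengths, tandem copies, microhomology
flanks), verifying at generation time that each constructed allele
classifies back to its intended channel.

## Problem sizes and numerical choices

The acceptance experiments use 600–1000 molecules on a 100 kb
reference, 100–200 somatic events, and 500 sampled calls for spectrum
recovery — sizes at which every rate of interest is measured on dozens
to hundreds of events while a full run completes in seconds. The
threshold sweep uses 2–6 reads per strand so that `a8s4`/`a10s5`
retain a non-trivial call subset. Ties and degenerate inputs: barcode
matching returns a rejection (never a guess) on ambiguity; merging
returns the pair unchanged when no offset passes the gates; the
`fraction=1` down-sample is the identity; zero spectra raise
`empty_spectrum` rather than returning 0; indels at contig edges raise
`context_unavailable` from the classifier.

## Known limitations

* Simple indels only (exactly one of ref/alt longer than the anchor);
  multi-nucleotide and complex variants are out of scope, as is SNV
  calling.
* No local realignment; representation differences are reconciled by
  left-normalization only.
* The bulk germline check is count-based, not genotype-aware; very low
  bulk depth is handled by conservative removal rather than modelling.
* Unmerged read pairs are carried through but the merge-confound filter
  can only vet merged reads (`not_evaluable` otherwise).
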