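"""End-to-end orchestration: BAM in, filtered somatic indel VCF out.

The pipeline mirrors the four calling stages — read preprocessing (done
upstream of alignment), molecule grouping by barcode pair, strand-aware
pileup with duplex-consensus thresholds, and the somatic filter stack —
and writes the intermediate candidate VCF, the final somatic VCF, a
single-strand track and a JSON run report with per-filter tallies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from duplexindel.molecules import group_molecules, load_duplex_reads, _read_indels
from duplexindel.pileup import (
    CallThreshold,
    GenomeMask,
    IndelAllele,
    ReferenceLookup,
    call_candidates,
    normalize_indel,
)
from duplexindel.filters import (
    BulkEvidence,
    BulkPileupTable,
    FilterConfig,
    PopulationAFDB,
    apply_filters,
    finalize_calls,
    write_candidate_vcf,
)


@dataclass
class RunConfig:
    """File paths and parameters for one pipeline run."""

    duplex_bam: str
    reference_fasta: str
    output_dir: str
    bulk_tsv: Optional[str] = None
    bulk_bam: Optional[str] = None
    mask_bed: Optional[str] = None
    af_tsv: Optional[str] = None
    a: int = 4
    s: int = 2
    min_mapq: int = 30
    min_bq: int = 20
    cutsite_tolerance: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0

    def validate(self) -> None:
        for path in (self.duplex_bam, self.reference_fasta, self.bulk_tsv,
                     self.bulk_bam, self.mask_bed, self.af_tsv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")
        if self.a < 1 or self.s < 0:
            raise ValueError("thresholds a, s must be positive")


def bulk_table_from_bam(bam_path: str, alleles: list[IndelAllele],
                        reference: ReferenceLookup,
                        min_mapq: int = 20) -> BulkPileupTable:
    """Compute bulk evidence for candidate alleles from a bulk WGS BAM.

    For each allele, counts bulk reads spanning the event that carry the
    same normalized indel (alt count) and all spanning reads (depth).
    """
    import pysam

    records: dict[IndelAllele, BulkEvidence] = {}
    site_depth: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for allele in set(alleles):
            start = allele.pos - 1
            end = start + len(allele.ref)
            depth = 0
            alt = 0
            for rec in bam.fetch(allele.chrom, max(0, start - 1), end + 1):
                if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                        or rec.is_duplicate or rec.mapping_quality < min_mapq):
                    continue
                if rec.reference_start > start or (rec.reference_end or 0) < end:
                    continue
                depth += 1
                for ev in _read_indels(rec):
                    anchor0 = ev.ref_pos
                    anchor = reference.fetch(allele.chrom, anchor0, anchor0 + 1)
                    if ev.kind == "D":
                        deleted = reference.fetch(allele.chrom, anchor0 + 1,
                                                  anchor0 + 1 + ev.length)
                        r, a = anchor + deleted, anchor
                    else:
                        r, a = anchor, anchor + ev.inserted
                    try:
                        norm = normalize_indel(allele.chrom, anchor0 + 1,
                                               r, a, reference)
                    except ValueError:
                        continue
                    if norm == allele:
                        alt += 1
                        break
            records[allele] = BulkEvidence(depth, min(alt, depth))
            site_depth[(allele.chrom, allele.pos)] = depth
    return BulkPileupTable(records, site_depth, default_depth=0)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run grouping, calling and filtering; write VCFs and the report.

    Deterministic given identical inputs. Returns the run report dict
    (also written as ``report.json`` in the output directory).
    """
    import pyfaidx

    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    fasta = pyfaidx.Fasta(cfg.reference_fasta, sequence_always_upper=True)
    reference = ReferenceLookup(fasta)
    contigs = [(name, len(fasta[name])) for name in fasta.keys()]

    reads = list(load_duplex_reads(cfg.duplex_bam, min_mapq=cfg.min_mapq))
    molecules = group_molecules(reads, cutsite_tolerance=cfg.cutsite_tolerance)

    mask = GenomeMask.from_bed(cfg.mask_bed) if cfg.mask_bed else None
    threshold = CallThreshold(a=cfg.a, s=cfg.s)
    candidates = call_candidates(
        molecules, reference, threshold,
        min_bq=cfg.min_bq, min_mapq=cfg.min_mapq, mask=mask,
    )

    with open(outdir / "candidates.vcf", "w") as fh:
        write_candidate_vcf(candidates, fh, contigs)

    bulk = None
    if cfg.bulk_tsv:
        bulk = BulkPileupTable.from_tsv(cfg.bulk_tsv)
    elif cfg.bulk_bam:
        bulk = bulk_table_from_bam(cfg.bulk_bam,
                                   [c.allele for c in candidates], reference)
    af_db = PopulationAFDB.from_tsv(cfg.af_tsv) if cfg.af_tsv else None

    apply_filters(candidates, cfg.filters, bulk=bulk, af_db=af_db,
                  reference=reference)

    with open(outdir / "somatic.vcf", "w") as out, \
            open(outdir / "single_strand.vcf", "w") as single_out:
        report = finalize_calls(candidates, out, single_out, contigs)

    report.update({
        "threshold": threshold.name,
        "n_reads": len(reads),
        "n_molecules": len(molecules),
        "n_molecules_cutsite_inconsistent": sum(
            1 for m in molecules if not m.cutsite_consistent),
    })
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
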