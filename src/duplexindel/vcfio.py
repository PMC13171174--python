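"""Small VCF reading helpers (cyvcf2-backed, with a text fallback)."""

from __future__ import annotations

from duplexindel.pileup import IndelAllele


def read_indel_vcf(path: str, pass_only: bool = True) -> list[IndelAllele]:
    """Read simple indels from a VCF; SNVs and symbolic alleles skipped."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_indel_vcf_text(path, pass_only)
    alleles: list[IndelAllele] = []
    for rec in VCF(path):
        if pass_only and rec.FILTER is not None:  # None means PASS in cyvcf2
            continue
        for alt in rec.ALT:
            if not alt or not alt[0].isalpha():
                continue
            if len(rec.REF) == len(alt):
                continue
            if min(len(rec.REF), len(alt)) != 1 or rec.REF[0] != alt[0]:
                continue
            alleles.append(IndelAllele(rec.CHROM, rec.POS, rec.REF, alt))
    return alleles


def _read_indel_vcf_text(path: str, pass_only: bool) -> list[IndelAllele]:
    alleles: list[IndelAllele] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: malformed VCF line")
            chrom, pos, _id, ref, alt_field, _qual, filt = parts[:7]
            if pass_only and filt not in ("PASS", "."):
                continue
            for alt in alt_field.split(","):
                if len(ref) == len(alt) or not alt[0].isalpha():
                    continue
                if min(len(ref), len(alt)) != 1 or ref[0] != alt[0]:
                    continue
                alleles.append(IndelAllele(chrom, int(pos), ref, alt))
    return alleles
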