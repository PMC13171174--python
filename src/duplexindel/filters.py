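"""Somatic filter stack and final call emission.

After duplex-consensus candidates are generated, a series of filters
removes germline variants and the artifact classes characteristic of
Tn5-based duplex sequencing:

* ``germline`` — the allele is also evidenced in matched bulk WGS
  (``low_bulk_depth`` conservatively removes sites the bulk cannot vet);
* ``merge_confound`` — the indel may be a false product of merging
  read-pair ends at the wrong offset in a tandem-repeat or microhomology
  context;
* ``near_germline`` — the candidate sits within a window of a distinct
  germline indel, where mapping errors concentrate;
* ``cutsite_inconsistent`` — the supporting molecule shows inconsistent
  Tn5 cut sites, i.e. a barcode collision between distinct molecules;
* ``common_variant`` — population allele frequency >= 1% (gnomAD-style
  table), indicating likely contamination rather than a somatic event.

Filters are label-based and commutative: each filter independently adds
its label to a candidate, and the final verdict is the label set. Every
filter can be switched off; disabling a filter can only grow the PASS set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO

from duplexindel.molecules import Molecule
from duplexindel.pileup import (
    IndelAllele,
    IndelCandidate,
    ReferenceLookup,
    Strandedness,
)

PASS_LABEL = "PASS"
FILTER_ORDER = [
    "germline",
    "low_bulk_depth",
    "merge_confound",
    "near_germline",
    "cutsite_inconsistent",
    "common_variant",
    "masked",
]


@dataclass(frozen=True)
class BulkEvidence:
    """Bulk WGS read support for one normalized indel allele."""

    bulk_depth: int
    bulk_alt_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.bulk_alt_count <= self.bulk_depth):
            raise ValueError("0 <= bulk_alt_count <= bulk_depth required")


class BulkPileupTable:
    """Bulk evidence lookup backed by a TSV pileup table.

    Columns: chrom, pos (1-based), ref, alt, depth, alt_count. Sites
    absent from the table are assumed covered at ``default_depth`` with
    zero alt reads (the table only needs rows where depth or alt support
    deviates from the default).
    """

    def __init__(self, records: Mapping[IndelAllele, BulkEvidence],
                 site_depth: Optional[Mapping[tuple[str, int], int]] = None,
                 default_depth: int = 30):
        self._records = dict(records)
        self._site_depth = dict(site_depth or {})
        self.default_depth = default_depth

    @classmethod
    def from_tsv(cls, path: str, default_depth: int = 30) -> "BulkPileupTable":
        records: dict[IndelAllele, BulkEvidence] = {}
        site_depth: dict[tuple[str, int], int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                chrom, pos, ref, alt, depth, alt_count = parts[:6]
                try:
                    allele = IndelAllele(chrom, int(pos), ref, alt)
                    ev = BulkEvidence(int(depth), int(alt_count))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                records[allele] = ev
                site_depth[(chrom, allele.pos)] = ev.bulk_depth
        return cls(records, site_depth, default_depth)

    def lookup(self, allele: IndelAllele) -> BulkEvidence:
        ev = self._records.get(allele)
        if ev is not None:
            return ev
        depth = self._site_depth.get((allele.chrom, allele.pos),
                                     self.default_depth)
        return BulkEvidence(bulk_depth=depth, bulk_alt_count=0)

    def germline_alleles(self, min_alt: int = 2,
                         min_vaf: float = 0.2) -> list[IndelAllele]:
        """Bulk-evidenced indels defining 'difficult regions' for the
        adjacency filter: alt count >= ``min_alt`` or VAF >= ``min_vaf``."""
        out = []
        for allele, ev in self._records.items():
            if ev.bulk_alt_count >= min_alt or (
                    ev.bulk_depth > 0
                    and ev.bulk_alt_count / ev.bulk_depth >= min_vaf):
                out.append(allele)
        return sorted(out)


class PopulationAFDB:
    """Population allele-frequency lookup (gnomAD-style local table).

    TSV columns: chrom, pos (1-based), ref, alt, AF. Alleles absent from
    the table have frequency 0.
    """

    def __init__(self, afs: Mapping[IndelAllele, float]):
        self._afs = dict(afs)

    @classmethod
    def from_tsv(cls, path: str) -> "PopulationAFDB":
        import gzip

        afs: dict[IndelAllele, float] = {}
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                chrom, pos, ref, alt, af = parts[:5]
                afs[IndelAllele(chrom, int(pos), ref, alt)] = float(af)
        return cls(afs)

    def af(self, allele: IndelAllele) -> float:
        return self._afs.get(allele, 0.0)


@dataclass
class FilterConfig:
    """Which filters run and how stringent each is."""

    enabled: set = field(default_factory=lambda: {
        "germline", "merge_confound", "near_germline",
        "cutsite_inconsistent", "common_variant",
    })
    germline_min_bulk_depth: int = 10
    adjacency_window: int = 10
    af_cutoff: float = 0.01
    require_cutsite_consistency: bool = True

    def __post_init__(self) -> None:
        if self.adjacency_window < 0:
            raise ValueError("adjacency_window must be >= 0")
        if not (0.0 <= self.af_cutoff <= 1.0):
            raise ValueError("af_cutoff must be in [0, 1]")


# ---------------------------------------------------------------------------
# Individual filters. Each returns the label it would attach, or None.
# ---------------------------------------------------------------------------

def germline_filter(cand: IndelCandidate, ev: BulkEvidence,
                    cfg: FilterConfig) -> Optional[str]:
    """Remove indels also evidenced in the matched bulk WGS sample.

    Any bulk alt read marks the allele germline; sites the bulk covers
    below ``germline_min_bulk_depth`` cannot be vetted and are removed
    conservatively as ``low_bulk_depth``.
    """
    if ev.bulk_alt_count >= 1:
        return "germline"
    if ev.bulk_depth < cfg.germline_min_bulk_depth:
        return "low_bulk_depth"
    return None


def merge_confound_filter(cand: IndelCandidate,
                          reference: ReferenceLookup) -> Optional[str]:
    """Flag indels that may be false products of read-pair merging.

    Merging read ends at a wrong offset in tandem-repeat or microhomology
    context fabricates indels. A candidate is flagged when every
    supporting read places the indel inside its merged-overlap interval
    and at least one of those merges was ambiguous, or when the indel's
    repeat tract (unit <= 6 bp, tract >= 12 bp) spans a merge boundary.

    Returns ``"not_evaluable"`` when supporting reads carry no merge
    metadata; callers treat that as a pass with a warning.
    """
    reads = cand.supporting_reads
    if not reads:
        return None
    with_meta = [r for r in reads if r.merged and r.overlap_ref is not None]
    if any(r.merged and r.overlap_ref is None for r in reads):
        return "not_evaluable"

    allele = cand.allele
    event_start = allele.pos - 1                       # 0-based anchor
    event_end = allele.pos - 1 + max(len(allele.ref), 1)

    if with_meta and len(with_meta) == len(reads):
        inside = all(r.overlap_ref[0] <= event_start
                     and event_end <= r.overlap_ref[1] for r in with_meta)
        if inside and any(r.ambiguous_merge for r in with_meta):
            return "merge_confound"
        # repeat tract spanning a merge boundary
        tract = _repeat_tract(reference, allele)
        if tract is not None:
            t_start, t_end = tract
            if t_end - t_start >= 12:
                for r in with_meta:
                    for boundary in r.overlap_ref:
                        if t_start < boundary < t_end:
                            return "merge_confound"
    return None


def _repeat_tract(reference: ReferenceLookup,
                  allele: IndelAllele) -> Optional[tuple[int, int]]:
    """Locate the tandem-repeat tract (unit <= 6 bp) containing the indel.

    Returns 0-based half-open reference coordinates of the longest tract
    found for any unit size, or None when no repeat of >= 2 units exists.
    """
    anchor0 = allele.pos - 1
    window = 60
    ctx_start = max(0, anchor0 - window)
    ctx = reference.fetch(allele.chrom, ctx_start, anchor0 + window)
    centre = anchor0 - ctx_start + 1  # first base after the anchor
    best: Optional[tuple[int, int]] = None
    for unit_len in range(1, 7):
        if centre + unit_len > len(ctx):
            continue
        unit = ctx[centre: centre + unit_len]
        if len(set(unit)) == 0:
            continue
        # extend left and right in whole units from the event position
        start = centre
        while start - unit_len >= 0 and ctx[start - unit_len: start] == unit:
            start -= unit_len
        end = centre
        while (end + unit_len <= len(ctx)
               and ctx[end: end + unit_len] == unit):
            end += unit_len
        if (end - start) // unit_len >= 2:
            tract = (ctx_start + start, ctx_start + end)
            if best is None or (tract[1] - tract[0]) > (best[1] - best[0]):
                best = tract
    return best


def adjacent_germline_filter(cand: IndelCandidate,
                             germline_indels: Sequence[IndelAllele],
                             window: int = 10) -> Optional[str]:
    """Flag candidates within ``window`` bp of a *distinct* germline indel
    (mapping errors concentrate around germline indels). The identical
    allele is the germline filter's job, not this one's."""
    for g in germline_indels:
        if g.chrom != cand.allele.chrom:
            continue
        if g == cand.allele:
            continue
        if abs(g.pos - cand.allele.pos) <= window:
            return "near_germline"
    return None


def cutsite_filter(cand: IndelCandidate,
                   molecule: Optional[Molecule] = None) -> Optional[str]:
    """Flag candidates from molecules with inconsistent Tn5 cut sites —
    the signature of a barcode collision between distinct molecules."""
    mol = molecule if molecule is not None else cand.molecule
    if not mol.cutsite_consistent:
        return "cutsite_inconsistent"
    return None


def population_af_filter(cand: IndelCandidate, db: PopulationAFDB,
                         af_cutoff: float = 0.01) -> Optional[str]:
    """Flag common indels (population AF >= cutoff, default 1%) as likely
    contamination rather than somatic events."""
    if db.af(cand.allele) >= af_cutoff:
        return "common_variant"
    return None


def apply_filters(
    candidates: Iterable[IndelCandidate],
    cfg: FilterConfig,
    bulk: Optional[BulkPileupTable] = None,
    af_db: Optional[PopulationAFDB] = None,
    reference: Optional[ReferenceLookup] = None,
    germline_indels: Optional[Sequence[IndelAllele]] = None,
) -> list[IndelCandidate]:
    """Evaluate every enabled filter on every candidate (in place).

    The label set is independent of evaluation order; each filter only
    ever adds its own label. Returns the candidates for chaining.
    """
    candidates = list(candidates)
    if germline_indels is None and bulk is not None:
        germline_indels = bulk.germline_alleles()
    for cand in candidates:
        if "germline" in cfg.enabled and bulk is not None:
            label = germline_filter(cand, bulk.lookup(cand.allele), cfg)
            if label:
                cand.filters.add(label)
        if "merge_confound" in cfg.enabled and reference is not None:
            label = merge_confound_filter(cand, reference)
            if label == "merge_confound":
                cand.filters.add(label)
        if "near_germline" in cfg.enabled and germline_indels is not None:
            label = adjacent_germline_filter(cand, germline_indels,
                                             cfg.adjacency_window)
            if label:
                cand.filters.add(label)
        if ("cutsite_inconsistent" in cfg.enabled
                and cfg.require_cutsite_consistency):
            label = cutsite_filter(cand)
            if label:
                cand.filters.add(label)
        if "common_variant" in cfg.enabled and af_db is not None:
            label = population_af_filter(cand, af_db, cfg.af_cutoff)
            if label:
                cand.filters.add(label)
    return candidates


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def molecule_hash(mol: Molecule) -> str:
    key = mol.key
    raw = f"{key.chrom}:{key.bc_lo}+{key.bc_hi}:{key.fragment_start}-{key.fragment_end}"
    return hashlib.sha1(raw.encode()).hexdigest()[:12]


VCF_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##INFO=<ID=NT,Number=1,Type=Integer,Description="Total alternative allele read count">',
    '##INFO=<ID=NP,Number=1,Type=Integer,Description="Alternative allele read count on plus strand">',
    '##INFO=<ID=NM,Number=1,Type=Integer,Description="Alternative allele read count on minus strand">',
    '##INFO=<ID=SD,Number=1,Type=String,Description="Strandedness: DOUBLE (duplex consensus) or SINGLE">',
    '##INFO=<ID=MOL,Number=.,Type=String,Description="Supporting molecule key hash(es)">',
    '##INFO=<ID=MOLN,Number=1,Type=Integer,Description="Number of supporting molecules">',
    '##FILTER=<ID=germline,Description="Allele evidenced in matched bulk WGS">',
    '##FILTER=<ID=low_bulk_depth,Description="Bulk depth too low to vet the site; removed conservatively">',
    '##FILTER=<ID=merge_confound,Description="Possible false indel from ambiguous read-pair merging">',
    '##FILTER=<ID=near_germline,Description="Within the adjacency window of a distinct germline indel">',
    '##FILTER=<ID=cutsite_inconsistent,Description="Supporting molecule shows inconsistent Tn5 cut sites (barcode collision)">',
    '##FILTER=<ID=common_variant,Description="Population allele frequency at or above the cutoff">',
    '##FILTER=<ID=masked,Description="Outside the supplied high-confidence genome mask">',
    '##FILTER=<ID=SINGLE_STRAND,Description="Alt support confined to one strand; fails the duplex complementarity check">',
]
VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def _candidate_record(cand: IndelCandidate, filter_field: str) -> str:
    a = cand.allele
    info = (f"NT={cand.n_total};NP={cand.n_plus};NM={cand.n_minus};"
            f"SD={cand.strandedness};MOL={molecule_hash(cand.molecule)}")
    return (f"{a.chrom}\t{a.pos}\t.\t{a.ref}\t{a.alt}\t.\t"
            f"{filter_field}\t{info}")


def write_candidate_vcf(candidates: Sequence[IndelCandidate],
                        out: TextIO, contigs: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Write the intermediate per-molecule candidate VCF."""
    _write_header(out, contigs)
    for cand in sorted(candidates, key=lambda c: (c.allele, molecule_hash(c.molecule))):
        out.write(_candidate_record(cand, PASS_LABEL if not cand.filters
                                    else _format_filters(cand.filters)) + "\n")


def _format_filters(labels: set) -> str:
    ordered = [l for l in FILTER_ORDER if l in labels]
    extra = sorted(labels - set(FILTER_ORDER))
    return ";".join(ordered + extra) if (ordered or extra) else PASS_LABEL


def _write_header(out: TextIO, contigs: Optional[Sequence[tuple[str, int]]]) -> None:
    for line in VCF_HEADER_LINES:
        out.write(line + "\n")
    for name, length in contigs or []:
        out.write(f"##contig=<ID={name},length={length}>\n")
    out.write(VCF_COLUMNS + "\n")


def finalize_calls(
    candidates: Sequence[IndelCandidate],
    out: TextIO,
    single_out: Optional[TextIO] = None,
    contigs: Optional[Sequence[tuple[str, int]]] = None,
) -> dict:
    """Collapse per-molecule candidates into final somatic VCF records.

    Double-strand candidates with an empty filter set become PASS
    records; filtered candidates are retained with their FILTER labels.
    Candidates at the same (chrom, pos, ref, alt) are collapsed into one
    record carrying the per-molecule support in INFO (MOLN molecules; NT/
    NP/NM summed over molecules); a site PASSes when at least one of its
    molecules passes. Single-strand calls go to a separate track
    (``single_out``) labelled SINGLE_STRAND — they are emitted for
    inspection but never PASS.

    Returns the run-report tally: candidate/PASS counts and per-filter
    removal counts (a multi-label candidate is counted once, under the
    first label in the fixed order, plus a multi-label tally).
    """
    double = [c for c in candidates if c.strandedness == Strandedness.DOUBLE]
    single = [c for c in candidates if c.strandedness == Strandedness.SINGLE]

    by_allele: dict[IndelAllele, list[IndelCandidate]] = {}
    for cand in double:
        by_allele.setdefault(cand.allele, []).append(cand)

    _write_header(out, contigs)
    report = {
        "candidates_double": len(double),
        "candidates_single": len(single),
        "pass": 0,
        "filtered": {label: 0 for label in FILTER_ORDER},
        "multi_label": 0,
        "sites": len(by_allele),
    }
    for allele in sorted(by_allele):
        group = by_allele[allele]
        passing = [c for c in group if not c.filters]
        if passing:
            filter_field = PASS_LABEL
        else:
            union: set = set()
            for c in group:
                union |= c.filters
            filter_field = _format_filters(union)
        nt = sum(c.n_total for c in group)
        np_ = sum(c.n_plus for c in group)
        nm = sum(c.n_minus for c in group)
        mols = ",".join(sorted(molecule_hash(c.molecule) for c in group))
        info = (f"NT={nt};NP={np_};NM={nm};SD=DOUBLE;"
                f"MOLN={len(group)};MOL={mols}")
        out.write(f"{allele.chrom}\t{allele.pos}\t.\t{allele.ref}\t"
                  f"{allele.alt}\t.\t{filter_field}\t{info}\n")
    for cand in double:
        if not cand.filters:
            report["pass"] += 1
        else:
            first = next(l for l in FILTER_ORDER if l in cand.filters)
            report["filtered"][first] += 1
            if len(cand.filters) > 1:
                report["multi_label"] += 1

    if single_out is not None:
        _write_header(single_out, contigs)
        for cand in sorted(single, key=lambda c: (c.allele,
                                                  molecule_hash(c.molecule))):
            labels = set(cand.filters) | {"SINGLE_STRAND"}
            ordered = [l for l in FILTER_ORDER if l in labels]
            field_ = ";".join(ordered + ["SINGLE_STRAND"])
            single_out.write(_candidate_record(cand, field_) + "\n")
    return report
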