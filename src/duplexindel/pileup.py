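"""Strand-aware indel pileup and duplex-consensus candidate calling.

Calling is threshold-based and operates at single-molecule resolution:
each molecule contributes at most one candidate per indel allele. A
candidate needs at least ``a`` alt-supporting reads in total; the duplex
complementarity check then requires at least ``s`` alt reads on *each*
strand for a double-strand (consensus) call. The default threshold is
a4s2. Candidates failing the per-strand check but reaching ``a`` in total
are labelled single-stranded — compatible with DNA damage or other
single-strand artifacts rather than true mutations.

Indel alleles are left-normalized against the reference so that the same
event observed at different alignment anchors (common in repeat tracts)
collapses to one representation, which also makes germline and
population-AF lookups exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from duplexindel.molecules import (
    SEX_CHROMOSOMES,
    AlignedDuplexRead,
    CigarIndel,
    Molecule,
    Strand,
)


class Strandedness:
    DOUBLE = "DOUBLE"
    SINGLE = "SINGLE"


@dataclass(frozen=True, order=True)
class IndelAllele:
    """A left-normalized simple indel in VCF anchor representation.

    ``pos`` is the 1-based anchor position; ``ref`` and ``alt`` share the
    anchor base, and exactly one of them has length 1.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def indel_seq(self) -> str:
        """The inserted or deleted bases (without the anchor)."""
        longer = self.alt if len(self.alt) > len(self.ref) else self.ref
        return longer[1:]


@dataclass(frozen=True)
class CallThreshold:
    """The aXsY threshold pair: ``a`` = minimum total alt reads, ``s`` =
    minimum alt reads on each strand (a4s2 by default)."""

    a: int = 4
    s: int = 2

    def __post_init__(self) -> None:
        if self.a < 1 or self.s < 0:
            raise ValueError("invalid threshold")

    @property
    def name(self) -> str:
        return f"a{self.a}s{self.s}"


@dataclass
class PileupColumn:
    """Per-position, per-strand allele read counts within one molecule."""

    chrom: str
    pos: int  # 1-based anchor position
    ref_base: str
    n_ref_plus: int = 0
    n_ref_minus: int = 0
    alt_plus: dict = field(default_factory=dict)   # IndelAllele -> count
    alt_minus: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return (self.n_ref_plus + self.n_ref_minus
                + sum(self.alt_plus.values()) + sum(self.alt_minus.values()))

    def n_alt_plus(self, allele: IndelAllele) -> int:
        return self.alt_plus.get(allele, 0)

    def n_alt_minus(self, allele: IndelAllele) -> int:
        return self.alt_minus.get(allele, 0)


@dataclass
class IndelCandidate:
    """One molecule's evidence for one indel allele, plus filter labels."""

    allele: IndelAllele
    molecule: Molecule
    n_plus: int
    n_minus: int
    strandedness: str
    filters: set = field(default_factory=set)
    supporting_reads: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def passes(self) -> bool:
        return not self.filters and self.strandedness == Strandedness.DOUBLE


class ReferenceLookup:
    """Uppercase base access over a pyfaidx Fasta or a plain dict of
    contig -> sequence string (0-based slicing either way)."""

    def __init__(self, source):
        self._src = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        if isinstance(self._src, Mapping):
            return str(self._src[chrom][start:end]).upper()
        return str(self._src[chrom][start:end]).upper()

    def contig_length(self, chrom: str) -> int:
        return len(self._src[chrom])


def normalize_indel(chrom: str, pos: int, ref: str, alt: str,
                    reference: ReferenceLookup) -> IndelAllele:
    """Left-normalize a simple indel to its minimal, leftmost anchor form.

    ``pos`` is 1-based. The allele is first reduced to a minimal
    representation (shared trailing/leading bases trimmed), then shifted
    left while the preceding reference base permits an equivalent
    representation — the standard VCF left-alignment procedure.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical")
    ref, alt = ref.upper(), alt.upper()
    ref_check = reference.fetch(chrom, pos - 1, pos - 1 + len(ref))
    if ref_check != ref:
        raise ValueError(
            f"allele inconsistent with reference at {chrom}:{pos} "
            f"({ref!r} vs {ref_check!r})")

    pos0 = pos - 1  # 0-based
    # shift left: trim equal trailing bases, re-extending with the
    # preceding reference base whenever an allele would become empty
    while ref and alt and ref[-1] == alt[-1]:
        if (len(ref) == 1 or len(alt) == 1) and pos0 == 0:
            break  # at contig start; cannot shift further
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            prev = reference.fetch(chrom, pos0 - 1, pos0)
            ref, alt = prev + ref, prev + alt
            pos0 -= 1
    # trim equal leading bases down to a single shared anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if not (min(len(ref), len(alt)) == 1 and ref[0] == alt[0]):
        raise ValueError(f"not a simple indel after normalization: {ref}>{alt}")
    return IndelAllele(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt)


def allele_from_cigar(read: AlignedDuplexRead, ev: CigarIndel,
                      reference: ReferenceLookup) -> IndelAllele:
    """Turn a CIGAR I/D event into a normalized IndelAllele."""
    anchor0 = ev.ref_pos
    anchor_base = reference.fetch(read.chrom, anchor0, anchor0 + 1)
    if ev.kind == "D":
        deleted = reference.fetch(read.chrom, anchor0 + 1, anchor0 + 1 + ev.length)
        ref, alt = anchor_base + deleted, anchor_base
    else:
        ref, alt = anchor_base, anchor_base + ev.inserted
    return normalize_indel(read.chrom, anchor0 + 1, ref, alt, reference)


def molecule_observations(
    molecule: Molecule,
    reference: ReferenceLookup,
    min_bq: int = 20,
    min_mapq: int = 30,
) -> dict[IndelAllele, dict[str, list[AlignedDuplexRead]]]:
    """Collect per-strand indel observations within one molecule.

    A read supports an allele when its alignment carries the event and
    the flanking base qualities (anchor base and first base after the
    event) are both >= ``min_bq``. Reads below ``min_mapq`` are ignored.
    """
    obs: dict[IndelAllele, dict[str, list[AlignedDuplexRead]]] = {}
    for read in molecule.reads:
        if read.mapq < min_mapq:
            continue
        seen: set[IndelAllele] = set()
        for ev in read.indels:
            if ev.qual_before < min_bq or ev.qual_after < min_bq:
                continue
            allele = allele_from_cigar(read, ev, reference)
            if allele in seen:
                continue  # one vote per read per allele
            seen.add(allele)
            slot = obs.setdefault(allele, {Strand.PLUS: [], Strand.MINUS: []})
            slot[read.strand].append(read)
    return obs


def pileup(
    molecules: Iterable[Molecule],
    reference: ReferenceLookup,
    min_bq: int = 20,
    min_mapq: int = 30,
) -> list[tuple[Molecule, dict[int, PileupColumn]]]:
    """Pile up each molecule's reads at candidate indel positions.

    Returns, per molecule, columns keyed by 1-based anchor position with
    per-strand reference and alternative counts. Reference support at a
    column counts reads that span the event footprint without carrying
    the allele.
    """
    out = []
    for mol in molecules:
        obs = molecule_observations(mol, reference, min_bq, min_mapq)
        columns: dict[int, PileupColumn] = {}
        for allele, by_strand in obs.items():
            col = columns.get(allele.pos)
            if col is None:
                col = PileupColumn(
                    chrom=allele.chrom, pos=allele.pos,
                    ref_base=reference.fetch(allele.chrom, allele.pos - 1,
                                             allele.pos),
                )
                columns[allele.pos] = col
            col.alt_plus[allele] = len(by_strand[Strand.PLUS])
            col.alt_minus[allele] = len(by_strand[Strand.MINUS])
        # reference support: spanning reads not carrying any alt at the column
        for pos, col in columns.items():
            footprint_end = max(
                pos - 1 + len(a.ref) for a in
                list(col.alt_plus) + list(col.alt_minus)
            )
            supporters = {
                r.read_id
                for a in set(col.alt_plus) | set(col.alt_minus)
                for strand_reads in obs.get(a, {}).values()
                for r in strand_reads
            }
            for read in mol.reads:
                if read.mapq < min_mapq or read.read_id in supporters:
                    continue
                if read.spans(pos - 1, footprint_end):
                    if read.strand == Strand.PLUS:
                        col.n_ref_plus += 1
                    else:
                        col.n_ref_minus += 1
        out.append((mol, columns))
    return out


def call_candidates(
    molecules: Iterable[Molecule],
    reference: ReferenceLookup,
    threshold: CallThreshold = CallThreshold(),
    min_bq: int = 20,
    min_mapq: int = 30,
    mask: Optional["GenomeMask"] = None,
    exclude_sex_chromosomes: bool = True,
) -> list[IndelCandidate]:
    """Emit per-molecule indel candidates under an aXsY threshold.

    One candidate per (molecule, allele) with at least ``threshold.a``
    alt reads in total. The complementarity check sets strandedness:
    DOUBLE iff each strand contributes >= ``threshold.s`` alt reads.
    Sex-chromosome candidates are excluded, as are positions outside the
    genome mask when one is supplied.
    """
    candidates: list[IndelCandidate] = []
    for mol in molecules:
        if exclude_sex_chromosomes and mol.key.chrom in SEX_CHROMOSOMES:
            continue
        obs = molecule_observations(mol, reference, min_bq, min_mapq)
        for allele in sorted(obs):
            by_strand = obs[allele]
            n_plus = len(by_strand[Strand.PLUS])
            n_minus = len(by_strand[Strand.MINUS])
            if n_plus + n_minus < threshold.a:
                continue
            if mask is not None and not mask.contains(allele.chrom, allele.pos - 1):
                continue
            double = n_plus >= threshold.s and n_minus >= threshold.s
            candidates.append(IndelCandidate(
                allele=allele,
                molecule=mol,
                n_plus=n_plus,
                n_minus=n_minus,
                strandedness=(Strandedness.DOUBLE if double
                              else Strandedness.SINGLE),
                supporting_reads=by_strand[Strand.PLUS] + by_strand[Strand.MINUS],
            ))
    candidates.sort(key=lambda c: (c.allele, c.molecule.key))
    return candidates


class GenomeMask:
    """High-confidence region mask from a BED file (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]]):
        from intervaltree import IntervalTree

        self._trees = {
            chrom: IntervalTree.from_tuples([(s, e) for s, e in ivs if e > s])
            for chrom, ivs in intervals.items()
        }

    @classmethod
    def from_bed(cls, path: str) -> "GenomeMask":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
                intervals.setdefault(parts[0], []).append((start, end))
        return cls(intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos0))
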