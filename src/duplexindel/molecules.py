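"""Group aligned duplex reads into single DNA molecules.

A Tn5-tagged molecule is identified by its barcode pair together with the
transposase cut sites (the fragment's reference start and end). Reads from
the two strands present the barcodes in opposite order, so the molecule key
uses the lexicographically ordered pair; strand is then recovered from the
read orientation. Two distinct molecules that happen to share a barcode
pair (a barcode collision) are detected by inconsistent cut sites and
flagged for downstream filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


class Strand:
    PLUS = "+"
    MINUS = "-"


@dataclass
class CigarIndel:
    """An insertion or deletion observed on a read's alignment.

    ``ref_pos`` is the 0-based reference position of the base *before*
    the event (the VCF anchor). ``seq`` holds the inserted read bases or
    the deleted reference span length.
    """

    kind: str            # "I" or "D"
    ref_pos: int         # 0-based anchor (base before the event)
    length: int
    inserted: str = ""   # read bases for insertions
    qual_before: int = 0
    qual_after: int = 0


@dataclass
class AlignedDuplexRead:
    """One aligned duplex read (typically an overlap-merged fragment read)."""

    read_id: str
    chrom: str
    fragment_start: int   # 0-based half-open template span on the reference
    fragment_end: int
    bc1: str
    bc2: str
    strand: str           # Strand.PLUS / Strand.MINUS
    mapq: int
    indels: list[CigarIndel] = field(default_factory=list)
    merged: bool = True
    overlap_ref: Optional[tuple[int, int]] = None  # merged-overlap interval on the reference
    ambiguous_merge: bool = False

    def spans(self, start: int, end: int) -> bool:
        """True if the read covers the reference interval [start, end)."""
        return self.fragment_start <= start and self.fragment_end >= end


@dataclass(frozen=True, order=True)
class MoleculeKey:
    chrom: str
    bc_lo: str
    bc_hi: str
    fragment_start: int
    fragment_end: int

    def __post_init__(self) -> None:
        if self.bc_lo > self.bc_hi:
            raise ValueError("barcodes must be lexicographically ordered")


@dataclass
class Molecule:
    """All reads sequenced from one original double-stranded fragment."""

    key: MoleculeKey
    reads_plus: list[AlignedDuplexRead] = field(default_factory=list)
    reads_minus: list[AlignedDuplexRead] = field(default_factory=list)
    cutsite_consistent: bool = True

    @property
    def reads(self) -> list[AlignedDuplexRead]:
        return self.reads_plus + self.reads_minus

    @property
    def n_reads(self) -> int:
        return len(self.reads_plus) + len(self.reads_minus)


def assign_strand(read: AlignedDuplexRead) -> str:
    """Return the strand label already carried by the read.

    Strand is determined by adaptor orientation: the read whose first
    barcode (bc1, sequenced at the 5' end of mate 1) sits at the leftmost
    reference coordinate of the fragment comes from the plus strand; the
    complementary strand presents the barcodes in the opposite order and
    aligns in the reverse orientation.
    """
    if read.strand not in (Strand.PLUS, Strand.MINUS):
        raise ValueError("unmapped")
    return read.strand


def _read_indels(rec: pysam.AlignedSegment) -> list[CigarIndel]:
    """Extract I/D events from a BAM record's CIGAR with flanking quals."""
    out: list[CigarIndel] = []
    quals = rec.query_qualities
    ref_pos = rec.reference_start
    query_pos = 0
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X
            ref_pos += length
            query_pos += length
        elif op == 1:  # I
            qb = quals[query_pos - 1] if quals is not None and query_pos > 0 else 60
            qa = (quals[query_pos + length] if quals is not None
                  and query_pos + length < len(quals) else 60)
            out.append(CigarIndel(
                kind="I", ref_pos=ref_pos - 1, length=length,
                inserted=rec.query_sequence[query_pos: query_pos + length],
                qual_before=qb, qual_after=qa,
            ))
            query_pos += length
        elif op == 2:  # D
            qb = quals[query_pos - 1] if quals is not None and query_pos > 0 else 60
            qa = (quals[query_pos] if quals is not None
                  and query_pos < len(quals) else 60)
            out.append(CigarIndel(
                kind="D", ref_pos=ref_pos - 1, length=length,
                qual_before=qb, qual_after=qa,
            ))
            ref_pos += length
        elif op == 4:  # S
            query_pos += length
        elif op == 3:  # N
            ref_pos += length
        # H/P consume nothing we track
    return out


def read_from_alignment(rec: pysam.AlignedSegment) -> Optional[AlignedDuplexRead]:
    """Convert a tagged BAM record into an AlignedDuplexRead.

    Requires the XB/XC barcode tags written by the alignment adapter.
    Returns None for unmapped, secondary or supplementary records.
    """
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return None
    try:
        bc1 = rec.get_tag("XB")
        bc2 = rec.get_tag("XC")
    except KeyError:
        return None
    merged = bool(rec.get_tag("XM")) if rec.has_tag("XM") else True
    overlap_len = int(rec.get_tag("XO")) if rec.has_tag("XO") else 0
    ambiguous = bool(rec.get_tag("XA")) if rec.has_tag("XA") else False
    start = rec.reference_start
    end = rec.reference_end
    overlap_ref: Optional[tuple[int, int]] = None
    if merged and overlap_len > 0:
        if rec.has_tag("XS"):
            ov_start = start + int(rec.get_tag("XS"))
        else:
            # without an explicit anchor, centre the overlap on the fragment
            ov_start = start + max(0, (end - start - overlap_len) // 2)
        overlap_ref = (ov_start, min(end, ov_start + overlap_len))
    return AlignedDuplexRead(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        fragment_start=start,
        fragment_end=end,
        bc1=bc1,
        bc2=bc2,
        strand=Strand.MINUS if rec.is_reverse else Strand.PLUS,
        mapq=rec.mapping_quality,
        indels=_read_indels(rec),
        merged=merged,
        overlap_ref=overlap_ref,
        ambiguous_merge=ambiguous,
    )


def load_duplex_reads(bam_path: str, min_mapq: int = 30,
                      region: Optional[str] = None) -> Iterator[AlignedDuplexRead]:
    """Stream tagged duplex reads from a coordinate-sorted BAM.

    Reads with mapping quality below ``min_mapq`` (default 30) are
    dropped before molecule grouping, as are unmapped / secondary /
    supplementary records and records lacking barcode tags.
    """
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        it = bam.fetch(region=region) if region else bam.fetch()
        for rec in it:
            read = read_from_alignment(rec)
            if read is None or read.mapq < min_mapq:
                continue
            yield read


def group_molecules(reads: Iterable[AlignedDuplexRead],
                    cutsite_tolerance: int = 0) -> list[Molecule]:
    """Partition reads into molecules by barcode pair and Tn5 cut sites.

    Reads sharing a (chrom, unordered barcode pair) and fragment
    coordinates equal within ``cutsite_tolerance`` bp form one molecule.
    Reads with the same barcode pair but cut sites differing beyond the
    tolerance are barcode collisions: they are split into distinct
    molecules, each flagged ``cutsite_consistent=False``.

    The result is a partition (every read in exactly one molecule) and
    is invariant to input read order.
    """
    by_pair: dict[tuple[str, str, str], list[AlignedDuplexRead]] = {}
    for read in reads:
        bc_lo, bc_hi = sorted((read.bc1, read.bc2))
        by_pair.setdefault((read.chrom, bc_lo, bc_hi), []).append(read)

    molecules: list[Molecule] = []
    for (chrom, bc_lo, bc_hi), group in sorted(by_pair.items()):
        # cluster by fragment coordinates within tolerance; sort for
        # order-invariance, then greedy single-linkage on both endpoints
        group.sort(key=lambda r: (r.fragment_start, r.fragment_end, r.read_id))
        clusters: list[list[AlignedDuplexRead]] = []
        for read in group:
            placed = False
            for cl in clusters:
                ref = cl[0]
                if (abs(read.fragment_start - ref.fragment_start) <= cutsite_tolerance
                        and abs(read.fragment_end - ref.fragment_end) <= cutsite_tolerance):
                    cl.append(read)
                    placed = True
                    break
            if not placed:
                clusters.append([read])
        consistent = len(clusters) == 1
        for cl in clusters:
            starts = min(r.fragment_start for r in cl)
            ends = max(r.fragment_end for r in cl)
            key = MoleculeKey(chrom, bc_lo, bc_hi, starts, ends)
            mol = Molecule(key=key, cutsite_consistent=consistent)
            for read in cl:
                if assign_strand(read) == Strand.PLUS:
                    mol.reads_plus.append(read)
                else:
                    mol.reads_minus.append(read)
            molecules.append(mol)
    return molecules
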