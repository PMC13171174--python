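"""Read preprocessing: barcode extraction, adapter trimming, overlap merging.

Raw duplex reads carry a terminal barcode on each mate (the Tn5 tag of one
fragment end). Preprocessing identifies the barcode pair against a reference
barcode list, strips the barcode bases, removes read-through sequencing
adapters, and merges the overlapping 3' ends of the two mates into a single
high-quality fragment read. Barcodes and merge metadata are propagated in
the read name so that an external aligner preserves them; the alignment
adapter (:func:`annotate_alignment`) lifts them back into BAM tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class RawReadPair:
    """A raw paired-end read: sequences plus per-base Phred qualities."""

    read_id: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence and quality lengths differ")


class BarcodeRef:
    """Reference list of valid terminal barcodes of uniform length.

    Parameters
    ----------
    barcodes
        DNA strings, all of the same length ``L_bc``.
    max_mismatch
        Maximum Hamming distance allowed when assigning an observed
        barcode to a reference barcode. Assignment is unambiguous when
        all pairwise distances in the list exceed ``2 * max_mismatch``.
    """

    def __init__(self, barcodes: Iterable[str], max_mismatch: int = 1):
        self.barcodes = [b.upper() for b in barcodes]
        if not self.barcodes:
            raise ValueError("empty barcode list")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError("barcodes must have uniform length")
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.length = lengths.pop()
        self.max_mismatch = max_mismatch
        self._exact = {b: b for b in self.barcodes}

    def match(self, observed: str) -> Optional[str]:
        """Assign ``observed`` to the unique reference barcode within
        ``max_mismatch``, or return None (no match, or ambiguous)."""
        observed = observed.upper()
        if len(observed) != self.length:
            return None
        hit = self._exact.get(observed)
        if hit is not None and self.max_mismatch >= 0:
            return hit
        best: Optional[str] = None
        for bc in self.barcodes:
            d = sum(1 for a, b in zip(observed, bc) if a != b)
            if d <= self.max_mismatch:
                if best is not None:
                    return None  # ambiguous
                best = bc
        return best


@dataclass
class MergeRecord:
    """Outcome of overlap merging for one read pair.

    ``ambiguous`` is set when a secondary overlap offset scores at least
    90% of the best offset's match count — the signature of tandem-repeat
    or microhomology read ends that can produce a false merge.
    """

    merged: bool
    overlap_len: int = 0
    overlap_start_in_fragment: int = 0
    ambiguous: bool = False


@dataclass
class ProcessedPair:
    """A read pair after barcode extraction / trimming / merging."""

    read_id: str
    bc1: str
    bc2: str
    merge: MergeRecord
    # merged read if merge.merged, else the two trimmed mates
    seq: str = ""
    qual: Sequence[int] = field(default_factory=list)
    seq1: str = ""
    seq2: str = ""
    qual1: Sequence[int] = field(default_factory=list)
    qual2: Sequence[int] = field(default_factory=list)


class BarcodeRejection(Exception):
    """Raised when a read pair cannot be assigned a barcode pair."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def extract_barcodes(pair: RawReadPair, ref: BarcodeRef) -> tuple[RawReadPair, str, str]:
    """Identify and strip the terminal barcode from each mate.

    The first ``L_bc`` bases of each mate are matched against the
    reference list within ``ref.max_mismatch``. Raises
    :class:`BarcodeRejection` with reason ``"too_short"`` if a mate is not
    longer than the barcode, or ``"no_match"`` / ``"ambiguous"`` style
    reasons when assignment fails.
    """
    L = ref.length
    if len(pair.seq1) < L + 1 or len(pair.seq2) < L + 1:
        raise BarcodeRejection("too_short")
    bc1 = ref.match(pair.seq1[:L])
    bc2 = ref.match(pair.seq2[:L])
    if bc1 is None or bc2 is None:
        raise BarcodeRejection("no_match")
    trimmed = RawReadPair(
        read_id=pair.read_id,
        seq1=pair.seq1[L:],
        seq2=pair.seq2[L:],
        qual1=pair.qual1[L:],
        qual2=pair.qual2[L:],
    )
    return trimmed, bc1, bc2


def trim_adapter(seq: str, qual: Sequence[int], adapter: str, min_match: int = 5) -> tuple[str, Sequence[int]]:
    """Remove a read-through adapter from the 3' end.

    The longest suffix of the read that exactly equals a prefix of
    ``adapter`` of length >= ``min_match`` is removed; if none exists the
    read is returned unchanged.
    """
    if min_match < 4:
        raise ValueError("min_match must be >= 4")
    adapter = adapter.upper()
    n = len(seq)
    best = 0
    longest = min(n, len(adapter))
    for k in range(longest, min_match - 1, -1):
        if seq[n - k:] == adapter[:k]:
            best = k
            break
    if best == 0:
        return seq, qual
    return seq[: n - best], qual[: n - best]


def merge_overlap(
    pair: RawReadPair,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
    ambiguity_margin: float = 0.9,
) -> tuple[ProcessedPair, MergeRecord]:
    """Merge the overlapping 3' ends of a read pair into one fragment read.

    Mate 2 is reverse-complemented onto the fragment orientation; every
    overlap offset of length >= ``min_overlap`` is scored by matching
    bases, and the best offset with mismatch fraction <=
    ``max_mismatch_rate`` is taken. In the overlap the base with the
    higher quality wins and keeps its quality; when the bases agree the
    quality is the max of the two. A second offset scoring at least
    ``ambiguity_margin`` of the best match count marks the merge
    ambiguous (tandem repeat / microhomology read ends).
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    s1, q1 = pair.seq1, list(pair.qual1)
    s2 = reverse_complement(pair.seq2)
    q2 = list(pair.qual2)[::-1]
    n1, n2 = len(s1), len(s2)

    best_offset = None
    best_matches = -1
    all_matches: list[tuple[int, int]] = []
    # offset = start of mate2 within the fragment coordinate of mate1
    # overlap spans [max(0, offset), min(n1, offset + n2))
    for offset in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo = max(0, offset)
        hi = min(n1, offset + n2)
        ov = hi - lo
        if ov < min_overlap:
            continue
        matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i - offset])
        if ov - matches > max_mismatch_rate * ov:
            continue  # only high-identity offsets are credible merges
        all_matches.append((offset, matches))
        if matches > best_matches:
            best_matches = matches
            best_offset = offset
    second_matches = max(
        (m for off, m in all_matches if off != best_offset), default=-1)

    if best_offset is None:
        rec = MergeRecord(merged=False)
        out = ProcessedPair(
            read_id=pair.read_id, bc1="", bc2="", merge=rec,
            seq1=s1, seq2=pair.seq2, qual1=q1, qual2=list(pair.qual2),
        )
        return out, rec

    offset = best_offset
    lo = max(0, offset)
    hi = min(n1, offset + n2)
    ambiguous = second_matches >= 0 and second_matches >= ambiguity_margin * best_matches

    # assemble fragment: mate1 prefix + consensus overlap + mate2 suffix
    frag_seq: list[str] = []
    frag_qual: list[int] = []
    if offset > 0:
        frag_seq.append(s1[:lo])
        frag_qual.extend(q1[:lo])
    else:
        frag_seq.append(s2[: -offset])
        frag_qual.extend(q2[: -offset])
    for i in range(lo, hi):
        b1, b2 = s1[i], s2[i - offset]
        c1, c2 = q1[i], q2[i - offset]
        if b1 == b2:
            frag_seq.append(b1)
            frag_qual.append(max(c1, c2))
        elif c1 >= c2:
            frag_seq.append(b1)
            frag_qual.append(c1)
        else:
            frag_seq.append(b2)
            frag_qual.append(c2)
    if offset + n2 > n1:
        frag_seq.append(s2[n1 - offset:])
        frag_qual.extend(q2[n1 - offset:])
    else:
        frag_seq.append(s1[hi:])
        frag_qual.extend(q1[hi:])

    rec = MergeRecord(
        merged=True,
        overlap_len=hi - lo,
        overlap_start_in_fragment=lo if offset > 0 else (lo - offset),
        ambiguous=ambiguous,
    )
    out = ProcessedPair(
        read_id=pair.read_id, bc1="", bc2="", merge=rec,
        seq="".join(frag_seq), qual=frag_qual,
    )
    return out, rec


def process_pair(
    pair: RawReadPair,
    ref: BarcodeRef,
    adapter: Optional[str] = None,
    min_match: int = 5,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> ProcessedPair:
    """Run barcode extraction, adapter trimming and merging on one pair."""
    trimmed, bc1, bc2 = extract_barcodes(pair, ref)
    s1, q1 = trimmed.seq1, trimmed.qual1
    s2, q2 = trimmed.seq2, trimmed.qual2
    if adapter:
        s1, q1 = trim_adapter(s1, q1, adapter, min_match)
        s2, q2 = trim_adapter(s2, q2, adapter, min_match)
    merged, rec = merge_overlap(
        RawReadPair(pair.read_id, s1, s2, q1, q2),
        min_overlap=min_overlap,
        max_mismatch_rate=max_mismatch_rate,
    )
    merged.bc1, merged.bc2 = bc1, bc2
    return merged


# ---------------------------------------------------------------------------
# FASTQ I/O.  Barcodes and merge metadata are carried in the read name as
# @<id>:BC:<bc1>+<bc2>:XM:<0|1>:XO:<overlap>:XA:<0|1> so they survive an
# external aligner; annotate_alignment() lifts them into BAM tags.
# ---------------------------------------------------------------------------

def _phred_str(qual: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in qual)


def read_fastq_pairs(fq1: TextIO, fq2: TextIO) -> Iterator[RawReadPair]:
    """Iterate a pair of 4-line FASTQ streams as RawReadPair records."""
    while True:
        h1 = fq1.readline().strip()
        if not h1:
            return
        s1 = fq1.readline().strip()
        fq1.readline()
        q1 = fq1.readline().strip()
        h2 = fq2.readline().strip()
        s2 = fq2.readline().strip()
        fq2.readline()
        q2 = fq2.readline().strip()
        rid = h1[1:].split()[0]
        yield RawReadPair(
            rid, s1, s2,
            [ord(c) - 33 for c in q1],
            [ord(c) - 33 for c in q2],
        )


def encode_name(read_id: str, p: ProcessedPair) -> str:
    m = p.merge
    return (
        f"{read_id}:BC:{p.bc1}+{p.bc2}:XM:{int(m.merged)}"
        f":XO:{m.overlap_len}:XA:{int(m.ambiguous)}"
        f":XS:{m.overlap_start_in_fragment}"
    )


def decode_name(name: str) -> tuple[str, dict]:
    """Split an annotated read name into (id, tag dict)."""
    parts = name.split(":BC:")
    if len(parts) != 2:
        return name, {}
    rid = parts[0]
    rest = parts[1].split(":")
    bcs = rest[0].split("+")
    tags = {"XB": bcs[0], "XC": bcs[1]}
    it = iter(rest[1:])
    for key in it:
        tags[key] = int(next(it))
    return rid, tags


def process_fastq(
    fq1: TextIO,
    fq2: TextIO,
    ref: BarcodeRef,
    out_merged: TextIO,
    out_r1: TextIO,
    out_r2: TextIO,
    adapter: Optional[str] = None,
    min_match: int = 5,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> dict:
    """Preprocess a FASTQ pair; returns counters for the run report.

    Merged pairs are written as single-end FASTQ to ``out_merged``;
    unmerged pairs to ``out_r1``/``out_r2``. All read names carry the
    barcode and merge annotation.
    """
    stats = {"total": 0, "rejected": 0, "merged": 0, "unmerged": 0,
             "ambiguous_merge": 0}
    for pair in read_fastq_pairs(fq1, fq2):
        stats["total"] += 1
        try:
            p = process_pair(pair, ref, adapter, min_match, min_overlap,
                             max_mismatch_rate)
        except BarcodeRejection:
            stats["rejected"] += 1
            continue
        name = encode_name(pair.read_id, p)
        if p.merge.merged:
            stats["merged"] += 1
            if p.merge.ambiguous:
                stats["ambiguous_merge"] += 1
            out_merged.write(f"@{name}\n{p.seq}\n+\n{_phred_str(p.qual)}\n")
        else:
            stats["unmerged"] += 1
            out_r1.write(f"@{name}\n{p.seq1}\n+\n{_phred_str(p.qual1)}\n")
            out_r2.write(f"@{name}\n{p.seq2}\n+\n{_phred_str(p.qual2)}\n")
    return stats


def annotate_alignment(bam_in: str, bam_out: str) -> int:
    """Alignment adapter: move name-encoded barcode/merge metadata into
    BAM tags XB/XC/XM/XO/XA and strip the annotation from the name.

    Returns the number of records written.
    """
    import pysam

    n = 0
    with pysam.AlignmentFile(bam_in, "rb", check_sq=False) as src:
        with pysam.AlignmentFile(bam_out, "wb", template=src) as dst:
            for rec in src:
                rid, tags = decode_name(rec.query_name)
                if tags:
                    rec.query_name = rid
                    for k, v in tags.items():
                        rec.set_tag(k, v)
                dst.write(rec)
                n += 1
    return n
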