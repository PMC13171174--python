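"""Ground-truthed synthetic duplex sequencing data.

The generator emulates a Tn5 duplex experiment end to end: a reference
with planted homopolymers and tandem repeats, barcoded molecules with
strand-split read families, germline and somatic indels, and every
artifact class the caller's filters target — single-strand events,
barcode collisions, ambiguous merges at repeat tracts and common
population variants — each independently switchable and recorded in a
truth set. Outputs cover both the raw path (barcoded FASTQ pairs for the
preprocessor) and the aligned path (tagged BAM records computed from the
known placement, so the caller is testable without an aligner), plus a
bulk pileup table carrying germline but not somatic evidence.

A ``mixture_fraction`` parameter restricts somatic events to a
subpopulation of molecules, emulating dilution experiments in which a
mutation-bearing cell line is mixed into a matched normal background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from duplexindel.molecules import AlignedDuplexRead, CigarIndel, MoleculeKey, Strand
from duplexindel.pileup import IndelAllele, ReferenceLookup, normalize_indel
from duplexindel.preprocess import reverse_complement
from duplexindel.filters import BulkEvidence, BulkPileupTable, PopulationAFDB
from duplexindel.spectrum import ID83_CHANNELS, classify_indel

BASES = "ACGT"
DEFAULT_QUAL = 37


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

@dataclass
class RepeatFeature:
    chrom: str
    start: int   # 0-based half-open
    end: int
    unit: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_reference(length: int = 100_000, seed: int = 0,
                       sex_length: int = 12_000,
                       feature_spacing: int = 5_000,
                       ) -> tuple[dict[str, str], list[RepeatFeature]]:
    """Simulate a reference genome with planted repeat features.

    Returns contig sequences (an autosome ``chr1`` plus a small ``chrX``
    to exercise sex-chromosome exclusion) and the coordinates of planted
    homopolymers (>= 8 bp) and tandem repeats (unit 2-6 bp), which
    exercise indel classification and merge-confound logic.
    Deterministic given ``seed``.
    """
    if length < 10_000:
        raise ValueError("length must be >= 10000")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))
    features: list[RepeatFeature] = []
    pos = feature_spacing
    kinds = ["homopolymer", 2, 3, 4, 5, 6]
    k = 0
    while pos + 40 < length - feature_spacing:
        kind = kinds[k % len(kinds)]
        if kind == "homopolymer":
            base = BASES[rng.integers(0, 4)]
            run = int(rng.integers(8, 13))
            tract = base * run
            unit = base
        else:
            unit = _random_seq(rng, kind)
            while len(set(unit)) == 1:
                unit = _random_seq(rng, kind)
            copies = max(2, int(np.ceil(14 / kind)))
            tract = unit * copies
        seq[pos: pos + len(tract)] = tract
        # break any accidental extension of the tract at its edges
        for edge in (pos - 1, pos + len(tract)):
            if 0 <= edge < length and seq[edge] == tract[0 if edge < pos else -1]:
                seq[edge] = BASES[(BASES.index(seq[edge]) + 1) % 4]
        features.append(RepeatFeature("chr1", pos, pos + len(tract), unit))
        k += 1
        pos += feature_spacing
    contigs = {
        "chr1": "".join(seq),
        "chrX": _random_seq(rng, sex_length),
    }
    return contigs, features


def write_fasta(contigs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------

def generate_barcodes(n: int, length: int = 8, min_distance: int = 3,
                      seed: int = 0) -> list[str]:
    """Random barcode list with pairwise Hamming distance >= ``min_distance``
    (unambiguous assignment at max_mismatch = (min_distance - 1) // 2)."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance
               for bc in out):
            out.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("cannot generate enough distinct barcodes")
    return out


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated duplex experiment."""

    seed: int
    ref_length: int = 100_000
    n_molecules: int = 1000
    n_sex_molecules: int = 5
    reads_per_strand: tuple[int, int] = (2, 3)       # inclusive range
    fragment_mean: float = 240.0
    fragment_sd: float = 25.0
    fragment_min: int = 180
    fragment_max: int = 280
    read_length: int = 160
    barcode_length: int = 8
    n_barcodes: int = 64
    adapter: str = "AGATCGGAAGAGC"
    n_germline: int = 30
    n_somatic: int = 200
    indel_max_len: int = 3
    single_strand_artifact_rate: float = 0.0
    artifact_strand_reads: tuple[int, int] = (4, 5)
    collision_rate: float = 0.0
    n_mismerge: int = 0
    n_common: int = 0
    common_af: float = 0.05
    seq_error_rate: float = 0.001
    mixture_fraction: float = 1.0
    bulk_depth: int = 30

    def __post_init__(self) -> None:
        for rate in (self.single_strand_artifact_rate, self.collision_rate,
                     self.seq_error_rate, self.mixture_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_somatic > self.n_molecules:
            raise ValueError("more somatic events than molecules")


@dataclass
class TruthSet:
    """Everything the simulator planted, for exact round-trip checks."""

    germline: list[tuple[IndelAllele, float]] = field(default_factory=list)
    somatic: list[tuple[IndelAllele, MoleculeKey]] = field(default_factory=list)
    artifacts: list[tuple[IndelAllele, str, MoleculeKey]] = field(default_factory=list)
    collisions: list[MoleculeKey] = field(default_factory=list)
    mismerges: list[tuple[IndelAllele, MoleculeKey]] = field(default_factory=list)
    common: list[tuple[IndelAllele, float, MoleculeKey]] = field(default_factory=list)
    sex_chrom: list[tuple[IndelAllele, MoleculeKey]] = field(default_factory=list)

    @property
    def somatic_alleles(self) -> set[IndelAllele]:
        return {a for a, _ in self.somatic}


@dataclass
class _MoleculeSpec:
    index: int
    chrom: str
    start: int
    end: int
    bc_left: str    # barcode at the leftmost fragment coordinate
    bc_right: str
    n_plus: int
    n_minus: int
    variants: list[IndelAllele] = field(default_factory=list)      # both strands
    strand_variants: dict = field(default_factory=lambda: {Strand.PLUS: [],
                                                           Strand.MINUS: []})
    collided: bool = False
    ambiguous_merge: bool = False
    overlap: Optional[tuple[int, int]] = None   # reference coords

    @property
    def key(self) -> MoleculeKey:
        lo, hi = sorted((self.bc_left, self.bc_right))
        return MoleculeKey(self.chrom, lo, hi, self.start, self.end)


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    reference: dict[str, str]
    features: list[RepeatFeature]
    barcodes: list[str]
    truth: TruthSet
    molecule_specs: list[_MoleculeSpec]
    reads: list[AlignedDuplexRead]
    bulk: BulkPileupTable
    af_db: PopulationAFDB
    af_rows: list[tuple[IndelAllele, float]]

    # ---- file emission -------------------------------------------------
    def write(self, outdir: str) -> dict[str, str]:
        """Write FASTA/FASTQ/BAM/bulk/AF/truth files; returns the paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": str(out / "reference.fa"),
            "bam": str(out / "duplex.bam"),
            "fastq1": str(out / "duplex_R1.fastq"),
            "fastq2": str(out / "duplex_R2.fastq"),
            "bulk": str(out / "bulk_pileup.tsv"),
            "af": str(out / "population_af.tsv"),
            "barcodes": str(out / "barcodes.txt"),
            "truth_somatic": str(out / "truth_somatic.vcf"),
            "truth_germline": str(out / "truth_germline.vcf"),
            "truth_tsv": str(out / "truth.tsv"),
            "config": str(out / "sim_config.json"),
        }
        write_fasta(self.reference, paths["reference"])
        import pysam
        pysam.faidx(paths["reference"])
        self.write_bam(paths["bam"])
        self.write_fastq(paths["fastq1"], paths["fastq2"])
        self.write_bulk_tsv(paths["bulk"])
        self.write_af_tsv(paths["af"])
        with open(paths["barcodes"], "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")
        self._write_truth_vcf(paths["truth_somatic"],
                              [a for a, _ in self.truth.somatic])
        self._write_truth_vcf(paths["truth_germline"],
                              [a for a, _ in self.truth.germline])
        self.write_truth_tsv(paths["truth_tsv"])
        with open(paths["config"], "w") as fh:
            json.dump(asdict(self.cfg), fh, indent=1, default=list)
            fh.write("\n")
        return paths

    def write_bam(self, path: str) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)}
                   for name, seq in self.reference.items()],
        }
        tid = {name: i for i, name in enumerate(self.reference)}
        records = []
        for read in self.reads:
            rec = pysam.AlignedSegment()
            rec.query_name = read.read_id
            rec.reference_id = tid[read.chrom]
            rec.reference_start = read.fragment_start
            rec.mapping_quality = read.mapq
            rec.flag = 16 if read.strand == Strand.MINUS else 0
            seq, cigar = self._read_seq_cigar(read)
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(
                chr(DEFAULT_QUAL + 33) * len(seq))
            rec.cigartuples = cigar
            rec.set_tag("XB", read.bc1)
            rec.set_tag("XC", read.bc2)
            rec.set_tag("XM", 1 if read.merged else 0)
            ov = read.overlap_ref
            rec.set_tag("XO", (ov[1] - ov[0]) if ov else 0)
            rec.set_tag("XA", 1 if read.ambiguous_merge else 0)
            if ov:
                rec.set_tag("XS", ov[0] - read.fragment_start)
            records.append(rec)
        records.sort(key=lambda r: (r.reference_id, r.reference_start,
                                    r.query_name))
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)
        pysam.index(path)

    def _read_seq_cigar(self, read: AlignedDuplexRead) -> tuple[str, list]:
        """Reconstruct the read sequence and CIGAR from its variant set."""
        ref = self.reference[read.chrom]
        seq_parts: list[str] = []
        cigar: list[tuple[int, int]] = []
        cur = read.fragment_start
        for ev in sorted(read.indels, key=lambda e: e.ref_pos):
            span = ev.ref_pos + 1 - cur
            seq_parts.append(ref[cur: ev.ref_pos + 1])
            cigar.append((0, span))
            if ev.kind == "I":
                seq_parts.append(ev.inserted)
                cigar.append((1, ev.length))
                cur = ev.ref_pos + 1
            else:
                cigar.append((2, ev.length))
                cur = ev.ref_pos + 1 + ev.length
        seq_parts.append(ref[cur: read.fragment_end])
        cigar.append((0, read.fragment_end - cur))
        cigar = [(op, ln) for op, ln in cigar if ln > 0]
        seq = "".join(seq_parts)
        # re-apply this read's recorded substitution errors; errors never
        # land inside inserted bases, keeping indel truth unambiguous
        errors = getattr(read, "_errors", ())
        if errors:
            ins_spans = []
            qpos = 0
            for op, ln in cigar:
                if op == 1:
                    ins_spans.append((qpos, qpos + ln))
                if op in (0, 1):
                    qpos += ln
            chars = list(seq)
            for idx, base in errors:
                if idx < len(chars) and not any(
                        s <= idx < e for s, e in ins_spans):
                    chars[idx] = base
            seq = "".join(chars)
        return seq, cigar

    def write_fastq(self, path1: str, path2: str) -> None:
        """Emit raw barcoded read pairs reproducing each merged read."""
        cfg = self.cfg
        insert_len = cfg.read_length - cfg.barcode_length
        qline = chr(DEFAULT_QUAL + 33)
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for read in self.reads:
                frag, _ = self._read_seq_cigar(read)
                if read.strand == Strand.PLUS:
                    bc_first, bc_second = read.bc1, read.bc2
                    fwd = frag
                else:
                    bc_first, bc_second = read.bc1, read.bc2
                    fwd = reverse_complement(frag)
                m1 = fwd[:insert_len]
                m2 = reverse_complement(fwd)[:insert_len]
                if len(m1) < insert_len:
                    m1 += cfg.adapter[: insert_len - len(m1)]
                if len(m2) < insert_len:
                    m2 += cfg.adapter[: insert_len - len(m2)]
                s1 = bc_first + m1
                s2 = bc_second + m2
                f1.write(f"@{read.read_id}\n{s1}\n+\n{qline * len(s1)}\n")
                f2.write(f"@{read.read_id}\n{s2}\n+\n{qline * len(s2)}\n")

    def write_bulk_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tdepth\talt_count\n")
            rows = []
            for allele, vaf in self.truth.germline:
                alt = int(round(vaf * self.cfg.bulk_depth))
                rows.append((allele, self.cfg.bulk_depth, alt))
            for allele, depth, alt in sorted(
                    rows, key=lambda r: (r[0].chrom, r[0].pos, r[0].ref, r[0].alt)):
                fh.write(f"{allele.chrom}\t{allele.pos}\t{allele.ref}\t"
                         f"{allele.alt}\t{depth}\t{alt}\n")

    def write_af_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\taf\n")
            for allele, af in sorted(self.af_rows,
                                     key=lambda r: (r[0].chrom, r[0].pos,
                                                    r[0].ref, r[0].alt)):
                fh.write(f"{allele.chrom}\t{allele.pos}\t{allele.ref}\t"
                         f"{allele.alt}\t{af}\n")

    def _write_truth_vcf(self, path: str, alleles: Sequence[IndelAllele]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, seq in self.reference.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for a in sorted(set(alleles)):
                fh.write(f"{a.chrom}\t{a.pos}\t.\t{a.ref}\t{a.alt}\t.\tPASS\t.\n")

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#class\tchrom\tpos\tref\talt\tdetail\n")
            rows = []
            for a, vaf in self.truth.germline:
                rows.append(("germline", a, f"vaf={vaf}"))
            for a, key in self.truth.somatic:
                rows.append(("somatic", a, f"molecule={key.fragment_start}-{key.fragment_end}"))
            for a, strand, key in self.truth.artifacts:
                rows.append(("single_strand_artifact", a, f"strand={strand}"))
            for a, key in self.truth.mismerges:
                rows.append(("mismerge", a, ""))
            for a, af, key in self.truth.common:
                rows.append(("common", a, f"af={af}"))
            for a, key in self.truth.sex_chrom:
                rows.append(("sex_chrom", a, ""))
            for cls, a, detail in rows:
                fh.write(f"{cls}\t{a.chrom}\t{a.pos}\t{a.ref}\t{a.alt}\t{detail}\n")

    # ---- in-memory accessors ------------------------------------------
    def reference_lookup(self) -> ReferenceLookup:
        return ReferenceLookup(self.reference)

    def molecules(self):
        from duplexindel.molecules import group_molecules
        return group_molecules(self.reads)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _random_indel(rng: np.random.Generator, ref: str, chrom: str, pos0: int,
                  max_len: int, lookup: ReferenceLookup) -> IndelAllele:
    """Construct a random simple indel anchored at 0-based ``pos0``."""
    kind = "DEL" if rng.random() < 0.5 else "INS"
    length = int(rng.integers(1, max_len + 1))
    anchor = ref[pos0]
    if kind == "DEL":
        r, a = ref[pos0: pos0 + 1 + length], anchor
    else:
        r, a = anchor, anchor + _random_seq(rng, length)
    return normalize_indel(chrom, pos0 + 1, r, a, lookup)


def _far_from(pos: int, used: list[int], min_dist: int) -> bool:
    return all(abs(pos - u) >= min_dist for u in used)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full ground-truthed duplex dataset.

    Somatic indels are placed on both strands of a single molecule;
    single-strand artifacts on one strand only (with a read family large
    enough to register at the default a4 threshold); barcode collisions
    reuse a barcode pair at a distant locus; mis-merges plant an indel
    inside an ambiguously merged overlap at a repeat tract. Bulk
    evidence contains germline but not somatic alleles. Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    reference, features = simulate_reference(cfg.ref_length, int(rng.integers(2**31)))
    lookup = ReferenceLookup(reference)
    chr1 = reference["chr1"]
    truth = TruthSet()

    barcodes = generate_barcodes(cfg.n_barcodes, cfg.barcode_length,
                                 seed=int(rng.integers(2**31)))
    pair_pool = [(i, j) for i in range(len(barcodes))
                 for j in range(i + 1, len(barcodes))]
    need = cfg.n_molecules + cfg.n_sex_molecules + cfg.n_mismerge + cfg.n_common
    if need > len(pair_pool):
        raise ValueError("not enough barcode pairs for the molecule count")
    rng.shuffle(pair_pool)
    pair_iter = iter(pair_pool)

    used_anchors: list[int] = []
    feature_anchors = [f.start for f in features] + [f.end for f in features]

    def place_allele(lo: int, hi: int, min_dist: int = 20,
                     avoid_features: bool = True,
                     max_tries: int = 200) -> Optional[IndelAllele]:
        for _ in range(max_tries):
            pos0 = int(rng.integers(lo, hi))
            allele = _random_indel(rng, chr1, "chr1", pos0,
                                   cfg.indel_max_len, lookup)
            a0 = allele.pos - 1
            if not _far_from(a0, used_anchors, min_dist):
                continue
            if avoid_features and not _far_from(a0, feature_anchors, 40):
                continue
            if a0 < lo or a0 + len(allele.ref) > hi:
                continue
            used_anchors.append(a0)
            return allele
        return None

    # ---- germline indels ------------------------------------------------
    germline: list[tuple[IndelAllele, float]] = []
    while len(germline) < cfg.n_germline:
        allele = place_allele(100, cfg.ref_length - 100)
        if allele is None:
            break
        vaf = 0.5 if rng.random() < 0.8 else 1.0
        germline.append((allele, vaf))
    truth.germline = germline

    # ---- molecules ------------------------------------------------------
    specs: list[_MoleculeSpec] = []
    insert_len = cfg.read_length - cfg.barcode_length

    def new_fragment() -> tuple[int, int]:
        fraglen = int(np.clip(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                              cfg.fragment_min, cfg.fragment_max))
        start = int(rng.integers(50, cfg.ref_length - fraglen - 50))
        return start, start + fraglen

    def make_spec(idx: int, chrom: str, start: int, end: int,
                  bcl: str, bcr: str) -> _MoleculeSpec:
        lo, hi = cfg.reads_per_strand
        return _MoleculeSpec(
            index=idx, chrom=chrom, start=start, end=end,
            bc_left=bcl, bc_right=bcr,
            n_plus=int(rng.integers(lo, hi + 1)),
            n_minus=int(rng.integers(lo, hi + 1)),
        )

    collided_pairs: list[_MoleculeSpec] = []
    for i in range(cfg.n_molecules):
        start, end = new_fragment()
        if specs and rng.random() < cfg.collision_rate:
            # reuse an earlier, not-yet-collided molecule's barcode pair
            partners = [s for s in specs
                        if not s.collided and s.chrom == "chr1"
                        and abs(s.start - start) > 1000]
            if partners:
                partner = partners[int(rng.integers(len(partners)))]
                spec = make_spec(i, "chr1", start, end,
                                 partner.bc_left, partner.bc_right)
                spec.collided = True
                partner.collided = True
                collided_pairs.append(spec)
                specs.append(spec)
                continue
        bi, bj = next(pair_iter)
        specs.append(make_spec(i, "chr1", start, end,
                               barcodes[bi], barcodes[bj]))

    # collided molecules get a planted double-strand indel so that the
    # cut-site filter has a candidate to label
    for spec in collided_pairs:
        allele = place_allele(spec.start + 10, spec.end - 10,
                              avoid_features=False)
        if allele is not None:
            spec.variants.append(allele)
    for spec in specs:
        if spec.collided:
            truth.collisions.append(spec.key)

    # ---- somatic indels -------------------------------------------------
    eligible = [s for s in specs if not s.collided]
    n_tumor = max(1, int(round(cfg.mixture_fraction * len(eligible))))
    tumor = eligible[:n_tumor]
    order = rng.permutation(len(tumor))
    placed = 0
    somatic_specs: list[_MoleculeSpec] = []
    for idx in order:
        if placed >= cfg.n_somatic:
            break
        spec = tumor[idx]
        allele = place_allele(spec.start + 10, spec.end - 10)
        if allele is None:
            continue
        spec.variants.append(allele)
        truth.somatic.append((allele, spec.key))
        somatic_specs.append(spec)
        placed += 1
    if placed < cfg.n_somatic:
        raise ValueError(
            f"could only place {placed}/{cfg.n_somatic} somatic indels; "
            "reference too small or too crowded")

    # ---- common population variants ------------------------------------
    af_rows: list[tuple[IndelAllele, float]] = []
    for _ in range(cfg.n_common):
        start, end = new_fragment()
        bi, bj = next(pair_iter)
        spec = make_spec(len(specs), "chr1", start, end,
                         barcodes[bi], barcodes[bj])
        allele = place_allele(start + 10, end - 10)
        if allele is None:
            continue
        spec.variants.append(allele)
        specs.append(spec)
        truth.common.append((allele, cfg.common_af, spec.key))
        af_rows.append((allele, cfg.common_af))
    # below-cutoff decoy rows on a few somatic alleles must not filter
    for allele, _key in truth.somatic[:3]:
        af_rows.append((allele, 0.005))

    # ---- single-strand artifacts ----------------------------------------
    for spec in specs:
        if spec.collided or spec.variants:
            continue
        if rng.random() < cfg.single_strand_artifact_rate:
            allele = place_allele(spec.start + 10, spec.end - 10)
            if allele is None:
                continue
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            spec.strand_variants[strand].append(allele)
            lo, hi = cfg.artifact_strand_reads
            boosted = int(rng.integers(lo, hi + 1))
            if strand == Strand.PLUS:
                spec.n_plus = boosted
            else:
                spec.n_minus = boosted
            truth.artifacts.append((allele, strand, spec.key))

    # ---- mis-merged molecules at planted repeat tracts -------------------
    tandem = [f for f in features if len(f.unit) >= 2
              and f.end - f.start >= 12]
    for t in range(cfg.n_mismerge):
        if not tandem:
            break
        feat = tandem[t % len(tandem)]
        # fragment centred on the tract; false deletion of one repeat unit
        mid = (feat.start + feat.end) // 2
        fraglen = int(np.clip(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                              cfg.fragment_min, cfg.fragment_max))
        start = max(50, mid - fraglen // 2)
        end = start + fraglen
        bi, bj = next(pair_iter)
        spec = make_spec(len(specs), "chr1", start, end,
                         barcodes[bi], barcodes[bj])
        unit_len = len(feat.unit)
        anchor0 = feat.start - 1
        ref_a = chr1[anchor0: anchor0 + 1 + unit_len]
        allele = normalize_indel("chr1", anchor0 + 1, ref_a, ref_a[0], lookup)
        spec.variants.append(allele)
        spec.ambiguous_merge = True
        ov_half = max(20, (feat.end - feat.start))
        spec.overlap = (max(spec.start, feat.start - ov_half),
                        min(end, feat.end + ov_half))
        specs.append(spec)
        truth.mismerges.append((allele, spec.key))

    # ---- sex-chromosome molecules ---------------------------------------
    chrx = reference["chrX"]
    lookup_x = lookup
    for i in range(cfg.n_sex_molecules):
        fraglen = int(np.clip(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                              cfg.fragment_min, cfg.fragment_max))
        start = int(rng.integers(50, len(chrx) - fraglen - 50))
        end = start + fraglen
        bi, bj = next(pair_iter)
        spec = make_spec(len(specs), "chrX", start, end,
                         barcodes[bi], barcodes[bj])
        pos0 = int(rng.integers(start + 10, end - 10))
        kind = "DEL" if rng.random() < 0.5 else "INS"
        anchor = chrx[pos0]
        if kind == "DEL":
            r, a = chrx[pos0: pos0 + 2], anchor
        else:
            r, a = anchor, anchor + _random_seq(rng, 1)
        allele = normalize_indel("chrX", pos0 + 1, r, a, lookup_x)
        spec.variants.append(allele)
        specs.append(spec)
        truth.sex_chrom.append((allele, spec.key))

    # ---- germline variants onto molecules -------------------------------
    # every retained germline allele must be reachable from the reads:
    # sites no molecule covers are dropped, and heterozygous sites force
    # at least one covering molecule onto the carrier haplotype
    carriers: dict[IndelAllele, int] = {a: 0 for a, _ in germline}
    covering: dict[IndelAllele, list[_MoleculeSpec]] = {a: [] for a, _ in germline}
    for spec in specs:
        if spec.chrom != "chr1":
            continue
        for allele, vaf in germline:
            a0 = allele.pos - 1
            if a0 >= spec.start + 2 and a0 + len(allele.ref) <= spec.end - 2:
                covering[allele].append(spec)
                if vaf == 1.0 or rng.random() < vaf:
                    spec.variants.append(allele)
                    carriers[allele] += 1
    for allele, vaf in germline:
        if carriers[allele] == 0 and covering[allele]:
            covering[allele][0].variants.append(allele)
    germline = [(a, v) for a, v in germline if covering[a]]
    truth.germline = germline

    # ---- reads ----------------------------------------------------------
    reads: list[AlignedDuplexRead] = []
    for spec in specs:
        ref_seq = reference[spec.chrom]
        fraglen_ref = spec.end - spec.start
        ov = spec.overlap
        if ov is None:
            ov_start = spec.start + max(0, fraglen_ref - insert_len)
            ov_end = spec.start + min(fraglen_ref, insert_len)
            ov = (ov_start, ov_end) if ov_end > ov_start else None
        for strand, count in ((Strand.PLUS, spec.n_plus),
                              (Strand.MINUS, spec.n_minus)):
            variants = sorted(set(spec.variants + spec.strand_variants[strand]),
                              key=lambda a: a.pos)
            events = []
            for a in variants:
                if a.kind == "DEL":
                    events.append(CigarIndel(
                        kind="D", ref_pos=a.pos - 1, length=a.length,
                        qual_before=DEFAULT_QUAL, qual_after=DEFAULT_QUAL))
                else:
                    events.append(CigarIndel(
                        kind="I", ref_pos=a.pos - 1, length=a.length,
                        inserted=a.indel_seq,
                        qual_before=DEFAULT_QUAL, qual_after=DEFAULT_QUAL))
            seq_len = fraglen_ref + sum(
                a.length if a.kind == "INS" else -a.length for a in variants)
            for k in range(count):
                if strand == Strand.PLUS:
                    bc1, bc2 = spec.bc_left, spec.bc_right
                else:
                    bc1, bc2 = spec.bc_right, spec.bc_left
                read = AlignedDuplexRead(
                    read_id=f"mol{spec.index}_{'p' if strand == Strand.PLUS else 'm'}{k}",
                    chrom=spec.chrom,
                    fragment_start=spec.start,
                    fragment_end=spec.end,
                    bc1=bc1, bc2=bc2,
                    strand=strand,
                    mapq=60,
                    indels=[CigarIndel(e.kind, e.ref_pos, e.length, e.inserted,
                                       e.qual_before, e.qual_after)
                            for e in events],
                    merged=True,
                    overlap_ref=ov,
                    ambiguous_merge=spec.ambiguous_merge,
                )
                n_err = rng.binomial(seq_len, cfg.seq_error_rate)
                errors = []
                for _ in range(n_err):
                    idx = int(rng.integers(0, seq_len))
                    errors.append((idx, BASES[int(rng.integers(0, 4))]))
                read._errors = tuple(errors)
                reads.append(read)

    reads.sort(key=lambda r: (r.chrom, r.fragment_start, r.read_id))

    bulk_records: dict[IndelAllele, BulkEvidence] = {}
    site_depth: dict[tuple[str, int], int] = {}
    for allele, vaf in germline:
        ev = BulkEvidence(cfg.bulk_depth, int(round(vaf * cfg.bulk_depth)))
        bulk_records[allele] = ev
        site_depth[(allele.chrom, allele.pos)] = cfg.bulk_depth
    bulk = BulkPileupTable(bulk_records, site_depth,
                           default_depth=cfg.bulk_depth)
    af_db = PopulationAFDB({a: af for a, af in af_rows})

    return SimulatedDataset(
        cfg=cfg, reference=reference, features=features, barcodes=barcodes,
        truth=truth, molecule_specs=specs, reads=reads, bulk=bulk,
        af_db=af_db, af_rows=af_rows,
    )


# ---------------------------------------------------------------------------
# Spectrum-driven allele sampling (for spectrum-recovery benchmarks)
# ---------------------------------------------------------------------------

_UNITS = {2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTG", 6: "ACGTGC"}


def _channel_core(channel: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """Build (core sequence, ref, alt) realizing one ID83 channel; the
    allele anchor is the first base of the core."""
    kind, ctx, ln, stratum = channel.split(".")
    n_val = 5 if stratum == "5+" else int(stratum)

    def pick(exclude: str) -> str:
        choices = [b for b in BASES if b not in exclude]
        return choices[int(rng.integers(len(choices)))]

    if ctx in ("C", "T"):
        base = ctx
        if kind == "DEL":
            run = n_val + 1
            x = pick(base)
            y = pick(base)
            core = x + base * run + y
            return core, x + base, x
        run = n_val
        x = pick(base)
        y = pick(base)
        core = x + base * run + y
        return core, x, x + base

    L = 6 if (ln == "5+" and ctx == "MH" and stratum == "5+") else (
        5 if ln == "5+" else int(ln))
    if ctx == "repeats":
        unit = _UNITS[L]
        x = pick(unit[-1] + unit[0])
        y = pick(unit[0] + unit[-1])
        if kind == "DEL":
            core = x + unit * (n_val + 1) + y
            return core, x + unit, x
        core = x + unit * n_val + y
        return core, x, x + unit
    # microhomology deletion
    m = n_val
    d = _UNITS.get(L, "ACGTGC")[:L]
    x = pick(d[-1] + d[0])
    z = pick(d[m] + d[0]) if m < L else pick(d[0])
    downstream = d[:m] + z
    core = x + d + downstream
    return core, x + d, x


def sample_alleles_from_spectrum(
    probs: Sequence[float], n: int, seed: int = 0,
    chrom: str = "sim_spectrum", flank: int = 55,
) -> tuple[dict[str, str], list[IndelAllele]]:
    """Sample ``n`` indel alleles from an 83-channel distribution.

    Builds a synthetic contig in which each sampled channel is realized
    by an explicit sequence context, and returns the contig together
    with the normalized alleles. Each constructed allele is verified to
    classify back to its intended channel (contexts are re-drawn on the
    rare occasions the random flanks confound the classification).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (83,) or probs.sum() <= 0:
        raise ValueError("probs must be an 83-vector with positive mass")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(83, size=n, p=probs)

    pieces: list[str] = []
    alleles: list[IndelAllele] = []
    offset = 0
    for ch_idx in draws:
        channel = ID83_CHANNELS[ch_idx]
        for _attempt in range(50):
            core, ref_a, alt_a = _channel_core(channel, rng)
            left = _random_seq(rng, flank)
            right = _random_seq(rng, flank)
            segment = left + core + right
            lookup = ReferenceLookup({chrom: "A" * offset + segment})
            anchor_pos = offset + flank + 1  # 1-based
            try:
                allele = normalize_indel(chrom, anchor_pos, ref_a, alt_a, lookup)
                if allele.pos != anchor_pos:
                    continue  # flank allowed a left shift; re-draw
                if classify_indel(allele, lookup) != channel:
                    continue
            except ValueError:
                continue
            pieces.append(segment)
            alleles.append(allele)
            offset += len(segment)
            break
        else:
            raise RuntimeError(f"could not realize channel {channel}")
    return {chrom: "".join(pieces)}, alleles
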