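"""Indel normalization, strand-aware pileup and aXsY candidate calling."""

import itertools

import numpy as np
import pytest

from duplexindel.molecules import (
    AlignedDuplexRead,
    CigarIndel,
    Molecule,
    MoleculeKey,
    Strand,
    group_molecules,
)
from duplexindel.pileup import (
    CallThreshold,
    GenomeMask,
    IndelAllele,
    ReferenceLookup,
    Strandedness,
    call_candidates,
    normalize_indel,
    pileup,
)


def _apply(seq, pos0, ref, alt):
    """Apply a VCF-style allele to a sequence (0-based anchor)."""
    assert seq[pos0: pos0 + len(ref)] == ref
    return seq[:pos0] + alt + seq[pos0 + len(ref):]


def _normalize_oracle(seq, pos, ref, alt):
    """Enumerate every equivalent simple-indel representation of the
    edited haplotype and return the leftmost minimal one."""
    edited = _apply(seq, pos - 1, ref, alt)
    is_ins = len(alt) > len(ref)
    k = abs(len(alt) - len(ref))
    hits = []
    for p0 in range(len(seq)):
        if is_ins:
            for unit in {seq[p0 + 1: p0 + 1 + k], edited[p0 + 1: p0 + 1 + k]}:
                if len(unit) != k:
                    continue
                r, a = seq[p0], seq[p0] + unit
                if (p0 + len(r) <= len(seq)
                        and _apply(seq, p0, r, a) == edited):
                    hits.append((p0 + 1, r, a))
        else:
            r = seq[p0: p0 + 1 + k]
            a = seq[p0]
            if len(r) == 1 + k and _apply(seq, p0, r, a) == edited:
                hits.append((p0 + 1, r, a))
    assert hits, "oracle found no representation"
    return min(hits)


class TestNormalizeIndel:
    def test_homopolymer_deletion_shifts_to_leftmost(self):
        seq = "GGCAAATGG"
        lookup = ReferenceLookup({"c": seq})
        # deletion of the last A, reported at the rightmost anchor
        out = normalize_indel("c", 5, "AA", "A", lookup)
        assert (out.pos, out.ref, out.alt) == _normalize_oracle(seq, 5, "AA", "A")
        assert (out.pos, out.ref, out.alt) == (3, "CA", "C")

    def test_minimal_indel_in_unique_context_is_fixed_point(self):
        seq = "GATCCGTA"
        lookup = ReferenceLookup({"c": seq})
        out = normalize_indel("c", 2, "AT", "A", lookup)
        assert (out.pos, out.ref, out.alt) == (2, "AT", "A")

    def test_insertion_in_homopolymer_shifts_to_run_start(self):
        seq = "GCTTTTTAG"
        lookup = ReferenceLookup({"c": seq})
        # T insertion reported inside the T-run
        out = normalize_indel("c", 6, "T", "TT", lookup)
        assert (out.pos, out.ref, out.alt) == _normalize_oracle(seq, 6, "T", "TT")
        assert out.pos == 2  # anchored at the C before the run

    def test_padded_representation_reduced_to_minimal(self):
        seq = "GGCAAATGG"
        lookup = ReferenceLookup({"c": seq})
        out = normalize_indel("c", 5, "AAT", "AT", lookup)  # padded del of A
        assert (out.pos, out.ref, out.alt) == (3, "CA", "C")

    def test_inconsistent_ref_raises(self):
        lookup = ReferenceLookup({"c": "ACGTACGT"})
        with pytest.raises(ValueError, match="inconsistent"):
            normalize_indel("c", 2, "GG", "G", lookup)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle_on_random_indels(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        # bias toward repetitive contexts where shifting matters
        if seed % 2:
            p = int(rng.integers(10, 40))
            seq = seq[:p] + "ATATATAT" + seq[p:]
        lookup = ReferenceLookup({"c": seq})
        pos0 = int(rng.integers(5, len(seq) - 8))
        k = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            ref, alt = seq[pos0: pos0 + 1 + k], seq[pos0]
        else:
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
            ref, alt = seq[pos0], seq[pos0] + ins
        out = normalize_indel("c", pos0 + 1, ref, alt, lookup)
        assert (out.pos, out.ref, out.alt) == _normalize_oracle(
            seq, pos0 + 1, ref, alt)

    def test_normalization_idempotent(self):
        lookup = ReferenceLookup({"c": "GGCAAAAATGG"})
        first = normalize_indel("c", 6, "AA", "A", lookup)
        again = normalize_indel("c", first.pos, first.ref, first.alt, lookup)
        assert first == again


SEQ = "T" + "ACGTTGCA" * 8  # simple reference for hand-built molecules
LOOKUP = ReferenceLookup({"chr1": SEQ})


def _mol_read(rid, strand, indels=(), start=0, end=len(SEQ), mapq=60):
    return AlignedDuplexRead(
        read_id=rid, chrom="chr1", fragment_start=start, fragment_end=end,
        bc1="AAAA", bc2="CCCC", strand=strand, mapq=mapq,
        indels=[CigarIndel(*ev) for ev in indels])


def _molecule(reads):
    return group_molecules(reads)[0]


DEL_AT_10 = ("D", 10, 1, "", 37, 37)  # 1-bp deletion anchored at pos0 10


class TestPileupCounts:
    def test_balanced_deletion_counts_per_strand(self):
        reads = ([_mol_read(f"p{i}", Strand.PLUS, [DEL_AT_10]) for i in range(3)]
                 + [_mol_read(f"m{i}", Strand.MINUS, [DEL_AT_10])
                    for i in range(3)])
        mol = _molecule(reads)
        (_, cols), = pileup([mol], LOOKUP)
        (col,) = cols.values()
        (allele,) = col.alt_plus
        assert col.n_alt_plus(allele) == 3
        assert col.n_alt_minus(allele) == 3
        assert col.n_ref_plus == col.n_ref_minus == 0
        assert col.depth == 6

    def test_reference_reads_counted_at_column(self):
        reads = ([_mol_read(f"p{i}", Strand.PLUS, [DEL_AT_10]) for i in range(2)]
                 + [_mol_read(f"m{i}", Strand.MINUS, [DEL_AT_10])
                    for i in range(2)]
                 + [_mol_read("p_ref", Strand.PLUS),
                    _mol_read("m_ref", Strand.MINUS)])
        mol = _molecule(reads)
        (_, cols), = pileup([mol], LOOKUP)
        (col,) = cols.values()
        assert col.n_ref_plus == 1 and col.n_ref_minus == 1
        assert col.depth == 6

    def test_low_mapq_read_excluded_from_counts(self):
        base = ([_mol_read(f"p{i}", Strand.PLUS, [DEL_AT_10]) for i in range(2)]
                + [_mol_read(f"m{i}", Strand.MINUS, [DEL_AT_10])
                   for i in range(2)])
        with_bad = base + [_mol_read("bad", Strand.PLUS, [DEL_AT_10], mapq=10)]
        (_, cols_a), = pileup([_molecule(base)], LOOKUP)
        (_, cols_b), = pileup([_molecule(with_bad)], LOOKUP)
        (a,), (b,) = cols_a.values(), cols_b.values()
        (allele,) = a.alt_plus
        assert b.n_alt_plus(allele) == a.n_alt_plus(allele) == 2

    def test_low_flanking_quality_support_excluded(self):
        lowq = ("D", 10, 1, "", 10, 37)  # anchor base quality below 20
        reads = ([_mol_read(f"p{i}", Strand.PLUS, [lowq]) for i in range(2)]
                 + [_mol_read(f"m{i}", Strand.MINUS, [DEL_AT_10])
                    for i in range(2)])
        (_, cols), = pileup([_molecule(reads)], LOOKUP)
        (col,) = cols.values()
        (allele,) = col.alt_minus
        assert col.n_alt_plus(allele) == 0
        assert col.n_alt_minus(allele) == 2

    def test_counts_match_bruteforce_recount(self, clean_dataset):
        """Pileup counts equal an independent recount over raw reads."""
        mols = clean_dataset.molecules()
        ref = clean_dataset.reference_lookup()
        piled = pileup(mols, ref)
        from duplexindel.pileup import allele_from_cigar
        for mol, cols in piled:
            for pos, col in cols.items():
                for allele in set(col.alt_plus) | set(col.alt_minus):
                    expect = {Strand.PLUS: 0, Strand.MINUS: 0}
                    for read in mol.reads:
                        if read.mapq < 30:
                            continue
                        for ev in read.indels:
                            if ev.qual_before < 20 or ev.qual_after < 20:
                                continue
                            if allele_from_cigar(read, ev, ref) == allele:
                                expect[read.strand] += 1
                    assert col.n_alt_plus(allele) == expect[Strand.PLUS]
                    assert col.n_alt_minus(allele) == expect[Strand.MINUS]


class TestCallCandidates:
    def _family(self, n_plus, n_minus):
        reads = ([_mol_read(f"p{i}", Strand.PLUS, [DEL_AT_10])
                  for i in range(n_plus)]
                 + [_mol_read(f"m{i}", Strand.MINUS, [DEL_AT_10])
                    for i in range(n_minus)])
        return _molecule(reads)

    @pytest.mark.parametrize("n_plus,n_minus,expect", [
        (2, 2, Strandedness.DOUBLE),   # a4s2 satisfied on both strands
        (4, 0, Strandedness.SINGLE),   # total reached, one strand only
        (3, 1, Strandedness.SINGLE),   # minus strand below s
    ])
    def test_complementarity_check(self, n_plus, n_minus, expect):
        cands = call_candidates([self._family(n_plus, n_minus)], LOOKUP,
                                CallThreshold(4, 2))
        assert len(cands) == 1
        assert cands[0].strandedness == expect
        assert (cands[0].n_plus, cands[0].n_minus) == (n_plus, n_minus)

    def test_below_total_threshold_no_candidate(self):
        cands = call_candidates([self._family(2, 1)], LOOKUP,
                                CallThreshold(4, 2))
        assert cands == []

    def test_sex_chromosome_candidates_excluded(self, dirty_dataset):
        mols = dirty_dataset.molecules()
        ref = dirty_dataset.reference_lookup()
        cands = call_candidates(mols, ref)
        assert dirty_dataset.truth.sex_chrom  # scenario is non-trivial
        assert all(c.allele.chrom not in ("chrX", "chrY") for c in cands)

    def test_genome_mask_restricts_candidates(self, clean_dataset):
        mols = clean_dataset.molecules()
        ref = clean_dataset.reference_lookup()
        unmasked = call_candidates(mols, ref)
        half = GenomeMask({"chr1": [(0, 50_000)]})
        masked = call_candidates(mols, ref, mask=half)
        expected = {c.allele for c in unmasked if c.allele.pos - 1 < 50_000}
        assert {c.allele for c in masked} == expected
        assert len(masked) < len(unmasked)

    def test_double_call_sets_nest_with_threshold(self, clean_dataset):
        """(a,s) <= (a',s') componentwise implies the stricter DOUBLE set
        is contained in the looser one."""
        mols = clean_dataset.molecules()
        ref = clean_dataset.reference_lookup()
        def doubles(a, s):
            return {(c.allele, c.molecule.key)
                    for c in call_candidates(mols, ref, CallThreshold(a, s))
                    if c.strandedness == Strandedness.DOUBLE}
        for (a1, s1), (a2, s2) in itertools.combinations(
                [(2, 1), (4, 2), (6, 3), (8, 4)], 2):
            assert doubles(a2, s2) <= doubles(a1, s1)

    def test_clean_simulation_full_double_recall(self, clean_dataset):
        """Artifact-free data with >=2 reads per strand: every somatic
        molecule yields a DOUBLE candidate at a4s2."""
        mols = clean_dataset.molecules()
        ref = clean_dataset.reference_lookup()
        doubles = {c.allele for c in call_candidates(mols, ref)
                   if c.strandedness == Strandedness.DOUBLE}
        assert clean_dataset.truth.somatic_alleles <= doubles

    def test_no_double_calls_at_artifact_sites(self, dirty_dataset):
        mols = dirty_dataset.molecules()
        ref = dirty_dataset.reference_lookup()
        cands = call_candidates(mols, ref)
        artifact_sites = {a for a, _, _ in dirty_dataset.truth.artifacts}
        assert artifact_sites  # scenario is non-trivial
        for c in cands:
            if c.allele in artifact_sites:
                assert c.strandedness == Strandedness.SINGLE
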