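"""The somatic filter stack: germline, merge-confound, adjacency,
cut-site consistency, population AF, and final call emission."""

import io
import itertools

import pytest

from duplexindel.filters import (
    BulkEvidence,
    BulkPileupTable,
    FilterConfig,
    PopulationAFDB,
    adjacent_germline_filter,
    apply_filters,
    cutsite_filter,
    finalize_calls,
    germline_filter,
    merge_confound_filter,
    population_af_filter,
)
from duplexindel.molecules import (
    AlignedDuplexRead,
    Molecule,
    MoleculeKey,
    Strand,
)
from duplexindel.pileup import (
    IndelAllele,
    IndelCandidate,
    ReferenceLookup,
    Strandedness,
    call_candidates,
)

CFG = FilterConfig()


def _cand(allele=None, reads=(), strandedness=Strandedness.DOUBLE,
          consistent=True):
    allele = allele or IndelAllele("chr1", 100, "CA", "C")
    key = MoleculeKey("chr1", "AAAA", "CCCC", 50, 350)
    mol = Molecule(key=key, cutsite_consistent=consistent)
    return IndelCandidate(allele=allele, molecule=mol, n_plus=2, n_minus=2,
                          strandedness=strandedness,
                          supporting_reads=list(reads))


class TestGermlineFilter:
    def test_heterozygous_bulk_evidence_labels_germline(self):
        assert germline_filter(_cand(), BulkEvidence(30, 15), CFG) == "germline"

    def test_single_bulk_alt_read_suffices(self):
        assert germline_filter(_cand(), BulkEvidence(40, 1), CFG) == "germline"

    def test_clean_deep_bulk_passes(self):
        assert germline_filter(_cand(), BulkEvidence(40, 0), CFG) is None

    def test_shallow_bulk_removed_conservatively(self):
        assert germline_filter(_cand(), BulkEvidence(5, 0), CFG) == "low_bulk_depth"

    def test_planted_germline_fully_separated_from_somatic(self, dirty_dataset):
        """All germline-origin candidates labeled; no somatic labeled."""
        ds = dirty_dataset
        cands = call_candidates(ds.molecules(), ds.reference_lookup())
        germ = {a for a, _ in ds.truth.germline}
        som = ds.truth.somatic_alleles
        n_germ = 0
        for c in cands:
            label = germline_filter(c, ds.bulk.lookup(c.allele), CFG)
            if c.allele in germ:
                assert label == "germline"
                n_germ += 1
            elif c.allele in som:
                assert label is None
        assert n_germ > 0


def _merge_read(rid, overlap=(80, 140), ambiguous=False, merged=True):
    return AlignedDuplexRead(
        read_id=rid, chrom="chr1", fragment_start=50, fragment_end=350,
        bc1="AAAA", bc2="CCCC", strand=Strand.PLUS, mapq=60,
        merged=merged, overlap_ref=overlap if merged else None,
        ambiguous_merge=ambiguous)


class TestMergeConfoundFilter:
    import numpy as _np
    LOOKUP = ReferenceLookup({"chr1": "".join(
        "ACGT"[i] for i in _np.random.default_rng(0).integers(0, 4, 1000))})

    def test_unambiguous_overlaps_pass(self):
        cand = _cand(reads=[_merge_read("a"), _merge_read("b")])
        assert merge_confound_filter(cand, self.LOOKUP) is None

    def test_ambiguous_merge_inside_overlap_labeled(self):
        cand = _cand(reads=[_merge_read("a"),
                            _merge_read("b", ambiguous=True)])
        assert merge_confound_filter(cand, self.LOOKUP) == "merge_confound"

    def test_event_outside_overlap_passes_despite_ambiguity(self):
        cand = _cand(reads=[_merge_read("a", overlap=(200, 260),
                                        ambiguous=True)])
        assert merge_confound_filter(cand, self.LOOKUP) is None

    def test_missing_merge_metadata_not_evaluable(self):
        read = _merge_read("a")
        read.overlap_ref = None
        cand = _cand(reads=[read])
        assert merge_confound_filter(cand, self.LOOKUP) == "not_evaluable"

    def test_repeat_tract_spanning_merge_boundary_labeled(self):
        # 14-bp AT tract with a deletion of one unit; the merge boundary
        # falls inside the tract
        seq = "G" * 100 + "AT" * 7 + "C" * 100
        lookup = ReferenceLookup({"chr1": seq})
        allele = IndelAllele("chr1", 100, "GAT", "G")
        cand = _cand(allele=allele,
                     reads=[_merge_read("a", overlap=(90, 105))])
        assert merge_confound_filter(cand, lookup) == "merge_confound"

    def test_simulated_mismerges_labeled(self, dirty_dataset):
        ds = dirty_dataset
        ref = ds.reference_lookup()
        cands = call_candidates(ds.molecules(), ref)
        mm = {a for a, _ in ds.truth.mismerges}
        assert mm  # scenario is non-trivial
        hits = [c for c in cands if c.allele in mm]
        assert hits
        assert all(merge_confound_filter(c, ref) == "merge_confound"
                   for c in hits)


class TestAdjacentGermlineFilter:
    GERMLINE = [IndelAllele("chr1", 106, "TAAAAA", "T")]

    def test_nearby_germline_indel_labels(self):
        assert adjacent_germline_filter(_cand(), self.GERMLINE, 10) == \
            "near_germline"

    def test_distant_germline_indel_passes(self):
        far = [IndelAllele("chr1", 150, "TAAAAA", "T")]
        assert adjacent_germline_filter(_cand(), far, 10) is None

    def test_identical_allele_is_not_adjacency(self):
        cand = _cand()
        assert adjacent_germline_filter(cand, [cand.allele], 10) is None

    def test_zero_window_only_same_position(self):
        same_pos = [IndelAllele("chr1", 100, "CAT", "C")]
        assert adjacent_germline_filter(_cand(), same_pos, 0) == "near_germline"
        off_by_one = [IndelAllele("chr1", 101, "AT", "A")]
        assert adjacent_germline_filter(_cand(), off_by_one, 0) is None


class TestCutsiteAndPopulationAF:
    def test_consistent_molecule_passes(self):
        assert cutsite_filter(_cand(consistent=True)) is None

    def test_collision_molecule_labeled(self):
        assert cutsite_filter(_cand(consistent=False)) == "cutsite_inconsistent"

    @pytest.mark.parametrize("af,expect", [
        (0.05, "common_variant"),   # common indel at 5%
        (0.01, "common_variant"),   # boundary: >= 1% is filtered
        (0.0099, None),             # strictly below the cutoff passes
    ])
    def test_af_cutoff_boundary(self, af, expect):
        cand = _cand()
        db = PopulationAFDB({cand.allele: af})
        assert population_af_filter(cand, db, 0.01) == expect

    def test_absent_allele_treated_as_af_zero(self):
        db = PopulationAFDB({})
        assert population_af_filter(_cand(), db, 0.01) is None


class TestFilterStack:
    def _run(self, ds, cfg=None, order_seed=None):
        cands = call_candidates(ds.molecules(), ds.reference_lookup())
        apply_filters(cands, cfg or FilterConfig(), bulk=ds.bulk,
                      af_db=ds.af_db, reference=ds.reference_lookup())
        return cands

    def test_pass_set_equals_planted_somatic_truth(self, clean_dataset):
        cands = self._run(clean_dataset)
        assert {c.allele for c in cands if c.passes} == \
            clean_dataset.truth.somatic_alleles

    def test_labels_independent_of_filter_application_order(self, dirty_dataset):
        """Applying single filters in any order yields the same labels
        as the stack: each filter only ever adds its own label."""
        ds = dirty_dataset
        ref = ds.reference_lookup()
        cfg = FilterConfig()
        germ = ds.bulk.germline_alleles()
        stack = {}
        for c in self._run(ds):
            stack[(c.allele, c.molecule.key)] = set(c.filters)
        cands = call_candidates(ds.molecules(), ref)
        steps = [
            lambda c: germline_filter(c, ds.bulk.lookup(c.allele), cfg),
            lambda c: merge_confound_filter(c, ref),
            lambda c: adjacent_germline_filter(c, germ, cfg.adjacency_window),
            lambda c: cutsite_filter(c),
            lambda c: population_af_filter(c, ds.af_db, cfg.af_cutoff),
        ]
        for perm in itertools.islice(itertools.permutations(steps), 0, 6, 2):
            for c in cands:
                labels = set()
                for step in perm:
                    label = step(c)
                    if label and label != "not_evaluable":
                        labels.add(label)
                assert labels == stack[(c.allele, c.molecule.key)]

    def test_disabling_filters_only_grows_pass_set(self, dirty_dataset):
        full = {(c.allele, c.molecule.key)
                for c in self._run(dirty_dataset) if c.passes}
        names = ["germline", "merge_confound", "near_germline",
                 "cutsite_inconsistent", "common_variant"]
        prev = full
        for k in range(len(names)):
            cfg = FilterConfig()
            cfg.enabled = set(names[k + 1:])
            cur = {(c.allele, c.molecule.key)
                   for c in self._run(dirty_dataset, cfg) if c.passes}
            assert prev <= cur
            prev = cur

    def test_every_artifact_class_labeled(self, dirty_dataset):
        ds = dirty_dataset
        cands = self._run(ds)
        by_allele = {}
        for c in cands:
            by_allele.setdefault(c.allele, []).append(c)
        for allele, _, _ in ds.truth.common:
            assert all("common_variant" in c.filters
                       for c in by_allele.get(allele, []))
        for allele, _ in ds.truth.mismerges:
            assert all("merge_confound" in c.filters
                       for c in by_allele.get(allele, []))
        coll = set(ds.truth.collisions)
        labeled = [c for c in cands if c.molecule.key in coll]
        assert labeled
        assert all("cutsite_inconsistent" in c.filters for c in labeled)


class TestFinalizeCalls:
    def test_pass_and_filtered_records_written(self, dirty_dataset):
        ds = dirty_dataset
        cands = call_candidates(ds.molecules(), ds.reference_lookup())
        apply_filters(cands, FilterConfig(), bulk=ds.bulk, af_db=ds.af_db,
                      reference=ds.reference_lookup())
        out, single = io.StringIO(), io.StringIO()
        report = finalize_calls(cands, out, single)
        body = [l for l in out.getvalue().splitlines()
                if not l.startswith("#")]
        assert len(body) == report["sites"]
        pass_alleles = {(l.split("\t")[0], int(l.split("\t")[1]),
                         l.split("\t")[3], l.split("\t")[4])
                        for l in body if l.split("\t")[6] == "PASS"}
        truth = {(a.chrom, a.pos, a.ref, a.alt)
                 for a in ds.truth.somatic_alleles}
        assert pass_alleles == truth

    def test_report_tallies_sum_to_candidate_count(self, dirty_dataset):
        ds = dirty_dataset
        cands = call_candidates(ds.molecules(), ds.reference_lookup())
        apply_filters(cands, FilterConfig(), bulk=ds.bulk, af_db=ds.af_db,
                      reference=ds.reference_lookup())
        report = finalize_calls(cands, io.StringIO(), io.StringIO())
        assert report["pass"] + sum(report["filtered"].values()) == \
            report["candidates_double"]

    def test_single_strand_track_never_pass(self, dirty_dataset):
        ds = dirty_dataset
        cands = call_candidates(ds.molecules(), ds.reference_lookup())
        apply_filters(cands, FilterConfig(), bulk=ds.bulk, af_db=ds.af_db,
                      reference=ds.reference_lookup())
        single = io.StringIO()
        finalize_calls(cands, io.StringIO(), single)
        body = [l for l in single.getvalue().splitlines()
                if not l.startswith("#")]
        assert body  # artifacts were simulated
        assert all("SINGLE_STRAND" in l.split("\t")[6] for l in body)
        assert all(l.split("\t")[6] != "PASS" for l in body)
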