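import numpy as np
import pytest

from refcurate.align import KmerIndex, anchor_align
from refcurate.model import AlignmentRecord, Assembly, CoverageTrack
from refcurate.scaffold import (CandidateBreakpoint, assign_contigs,
                                build_chromosomes, classify_breakpoints,
                                filter_haplotype_duplicates,
                                find_candidate_breakpoints, self_align,
                                split_contigs, tile)
from refcurate.simulate import plant_duplicate_contigs, simulate_genome
from tests.conftest import small_config


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _rec(q, qlen, qs, qe, t, tlen, ts, te, strand="+", ident=1.0):
    span = max(qe - qs, te - ts)
    return AlignmentRecord(q, qlen, qs, qe, strand, t, tlen, ts, te,
                           int(span * ident), span)


class TestDuplicateFilter:
    def test_exact_contained_duplicate_removed(self, rng):
        big = random_seq(rng, 40_000)
        contigs = Assembly({"big": big, "small": big[5_000:15_000]})
        kept, removed = filter_haplotype_duplicates(contigs, self_align(contigs))
        assert "small" not in kept
        assert "big" in kept
        assert removed[0]["contig"] == "small"

    def test_identity_at_exactly_97_percent_is_kept(self, rng):
        """The removal rule is strictly greater-than the 97% threshold."""
        big = random_seq(rng, 40_000)
        piece = list(big[5_000:15_000])
        # exactly 3.0% mismatches -> aggregate identity 0.970, not > 0.97
        for p in np.linspace(50, len(piece) - 50, 300, dtype=int):
            piece[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[piece[p]]
        contigs = Assembly({"big": big, "small": "".join(piece)})
        alns = {"small": [_rec("small", 10_000, 0, 10_000, "big", 40_000,
                               5_000, 15_000, ident=0.97)]}
        kept, removed = filter_haplotype_duplicates(contigs, alns)
        assert "small" in kept and removed == []

    def test_planted_duplicates_exactly_recovered(self, ds_small, rng):
        dup_contigs, planted = plant_duplicate_contigs(ds_small.contigs, 4, rng)
        kept, removed = filter_haplotype_duplicates(dup_contigs,
                                                    self_align(dup_contigs))
        assert sorted(r["contig"] for r in removed) == sorted(planted)
        assert set(kept.names()) == set(ds_small.contigs.names())

    def test_threshold_must_be_in_unit_interval(self, ds_small):
        with pytest.raises(ValueError):
            filter_haplotype_duplicates(ds_small.contigs, {}, identity_threshold=1.5)


class TestAssign:
    def test_end_to_end_alignment_assigns_plus(self):
        alns = {"c": [_rec("c", 10_000, 0, 10_000, "chr1", 100_000, 0, 10_000)]}
        assignments, unplaced = assign_contigs(alns)
        assert assignments == {"c": ("chr1", "+")} and unplaced == []

    def test_majority_bases_decide_chromosome_and_strand(self):
        alns = {"c": [
            _rec("c", 10_000, 0, 7_000, "chr2", 100_000, 0, 7_000, "-"),
            _rec("c", 10_000, 7_000, 10_000, "chr3", 100_000, 0, 3_000, "+"),
        ]}
        assignments, _ = assign_contigs(alns)
        assert assignments["c"] == ("chr2", "-")

    def test_short_alignments_ignored_and_unplaced_reported(self):
        alns = {"c": [_rec("c", 10_000, 0, 1_500, "chr1", 100_000, 0, 1_500)]}
        assignments, unplaced = assign_contigs(alns)
        assert assignments == {} and unplaced == ["c"]

    def test_tie_breaks_lexicographically(self):
        alns = {"c": [
            _rec("c", 10_000, 0, 4_000, "chrB", 100_000, 0, 4_000),
            _rec("c", 10_000, 5_000, 9_000, "chrA", 100_000, 0, 4_000),
        ]}
        assignments, _ = assign_contigs(alns)
        assert assignments["c"][0] == "chrA"

    def test_synthetic_non_chimeric_contigs_assigned_to_truth(self, ds_small):
        t = ds_small.truth
        index = KmerIndex(ds_small.reference)
        chimeric = {c.contig for c in t.chimeras}
        ok = total = 0
        for name in ds_small.contigs.names():
            if name in chimeric:
                continue
            recs = anchor_align(ds_small.contigs[name], index, query_name=name)
            assignments, _ = assign_contigs({name: recs})
            if name not in assignments:
                continue
            total += 1
            truth_chrom = t.tiling[name][0].chrom
            # translocated tails legitimately map to the donor partner
            ok += assignments[name][0] == truth_chrom or any(
                tr for tr in t.translocations
                if truth_chrom in (tr.chrom_a, tr.chrom_b))
        assert total > 0 and ok / total >= 0.99


class TestBreakpoints:
    def test_full_length_alignment_yields_no_candidates(self):
        alns = [_rec("c", 50_000, 0, 50_000, "chr1", 100_000, 0, 50_000)]
        assert find_candidate_breakpoints("c", 50_000, alns) == []

    def test_end_within_5kb_of_contig_end_is_not_a_candidate(self):
        # alignment ends 4 kb from the contig end: inside the margin
        alns = [_rec("c", 50_000, 0, 46_000, "chr1", 100_000, 0, 46_000)]
        assert find_candidate_breakpoints("c", 50_000, alns) == []
        # 6 kb from the end: outside the margin, reported
        alns = [_rec("c", 50_000, 0, 44_000, "chr1", 100_000, 0, 44_000)]
        cands = find_candidate_breakpoints("c", 50_000, alns)
        assert [c.position for c in cands] == [44_000]

    def test_nearby_ends_merge_to_median(self):
        alns = [
            _rec("c", 50_000, 0, 20_000, "chr1", 100_000, 0, 20_000),
            _rec("c", 50_000, 20_400, 50_000, "chr2", 100_000, 0, 29_600),
        ]
        cands = find_candidate_breakpoints("c", 50_000, alns)
        assert len(cands) == 1
        assert 20_000 <= cands[0].position <= 20_400

    def test_uniform_coverage_leaves_candidates_unconfirmed(self):
        track = CoverageTrack({"c": [(0, 50_000, 30.0)]})
        cands = [CandidateBreakpoint("c", 25_000)]
        out = classify_breakpoints(cands, track)
        assert out[0].classification == "unconfirmed"
        assert out[0].split_position is None

    def test_low_coverage_confirms_and_splits_at_weak_point(self):
        track = CoverageTrack({"c": [(0, 33_000, 30.0), (33_000, 35_000, 2.0),
                                     (35_000, 50_000, 30.0)]})
        out = classify_breakpoints([CandidateBreakpoint("c", 25_000)], track)
        assert out[0].classification == "low-coverage"
        assert out[0].split_position == 34_000  # center of the trough

    def test_high_coverage_splits_at_the_alignment_breakpoint(self):
        track = CoverageTrack({"c": [(0, 20_000, 30.0), (20_000, 30_000, 40.0),
                                     (30_000, 50_000, 30.0)]})
        out = classify_breakpoints([CandidateBreakpoint("c", 25_000)], track)
        assert out[0].classification == "high-coverage"
        assert out[0].split_position == 25_000

    def test_coverage_exactly_at_thresholds(self):
        # 3x is low (<=); 35x is not high (>)
        track = CoverageTrack({"c": [(0, 50_000, 35.0)]})
        out = classify_breakpoints([CandidateBreakpoint("c", 25_000)], track)
        assert out[0].classification == "unconfirmed"
        track = CoverageTrack({"c": [(0, 50_000, 3.0)]})
        out = classify_breakpoints([CandidateBreakpoint("c", 25_000)], track)
        assert out[0].classification == "low-coverage"


class TestSplit:
    def test_no_confirmed_candidates_leaves_contigs_intact(self, ds_small):
        out, rename = split_contigs(ds_small.contigs,
                                    [CandidateBreakpoint("contig0001", 10_000)])
        assert out.sequences == ds_small.contigs.sequences

    def test_split_pieces_concatenate_to_original(self, rng):
        seq = random_seq(rng, 30_000)
        contigs = Assembly({"c": seq})
        out, rename = split_contigs(contigs, [
            CandidateBreakpoint("c", 12_345, "low-coverage", 12_345)])
        assert rename["c"] == ["c.1", "c.2"]
        assert out["c.1"] + out["c.2"] == seq
        assert len(out["c.1"]) == 12_345

    def test_total_bases_conserved_by_splitting(self, ds_small):
        cands = [CandidateBreakpoint(c.contig, c.offset, "low-coverage", c.offset)
                 for c in ds_small.truth.chimeras]
        out, _ = split_contigs(ds_small.contigs, cands)
        assert out.total_length() == ds_small.contigs.total_length()


class TestBuild:
    def test_two_contigs_with_projected_gap(self, rng):
        donor_seq = random_seq(rng, 200_000)
        donor = Assembly({"chr1": donor_seq})
        contigs = Assembly({"a": donor_seq[:100_000],
                            "b": donor_seq[110_000:200_000]})
        index = KmerIndex(donor)
        alns = {n: anchor_align(contigs[n], index, query_name=n)
                for n in contigs.names()}
        assignments, _ = assign_contigs(alns)
        chroms, plan, unplaced = build_chromosomes(assignments, alns, contigs)
        gaps = plan.gaps("chr1")
        assert len(gaps) == 1
        assert gaps[0].size == pytest.approx(10_000, abs=50)
        assert len(unplaced) == 0

    def test_minus_strand_contig_reverse_complemented(self, rng):
        from refcurate.model import revcomp
        donor_seq = random_seq(rng, 60_000)
        donor = Assembly({"chr1": donor_seq})
        contigs = Assembly({"a": revcomp(donor_seq[10_000:50_000])})
        index = KmerIndex(donor)
        alns = {"a": anchor_align(contigs["a"], index, query_name="a")}
        assignments, _ = assign_contigs(alns)
        assert assignments["a"] == ("chr1", "-")
        chroms, plan, _ = build_chromosomes(assignments, alns, contigs)
        assert chroms["chr1"] == donor_seq[10_000:50_000]
        assert plan.segments("chr1")[0].orientation == "-"

    def test_reconstruction_matches_truth_outside_withheld(self):
        """End-to-end tiling on a translocation-free genome reproduces the
        consensus haplotype exactly, slice for slice."""
        ds = simulate_genome(small_config(seed=19, translocation_count=0,
                                          chromosome_lengths=(150_000, 150_000)))
        t = ds.truth
        chroms, plan, unplaced, _ = tile(ds.contigs, ds.reference, ds.coverage)
        for chrom in chroms.names():
            expected = t.consensus[chrom]
            for s, e in sorted(((s, e) for c, s, e in t.withheld if c == chrom),
                               reverse=True):
                expected = expected[:s] + expected[e:]
            assert chroms[chrom].replace("N", "") == expected.replace("N", "")

    def test_non_n_bases_conserved_through_tiling(self, ds_small):
        chroms, plan, unplaced, _ = tile(ds_small.contigs, ds_small.reference,
                                         ds_small.coverage)
        def non_n(asm):
            return sum(1 for s in asm.sequences.values() for c in s
                       if c not in "Nn")
        assert non_n(chroms) + non_n(unplaced) == non_n(ds_small.contigs)
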