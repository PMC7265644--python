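import math

import numpy as np
import pytest

from refcurate.align import KmerIndex
from refcurate.model import Assembly, GenotypedVariant
from refcurate.varbench import (apply_corrections, benchmark_assembly,
                                call_small_variants, compare_small_variants,
                                compute_qv, modified_fp_filter,
                                normalize_variant, plan_corrections,
                                sv_presence)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestNormalize:
    def test_snv_unchanged(self):
        assert normalize_variant("AAACAAA", 3, "C", "G") == (3, "C", "G")

    def test_right_trim_and_left_align_in_homopolymer(self):
        # deletion of one T inside TTTT: every representation normalizes
        # to the leftmost anchored form
        seq = "ACGTTTTACG"
        assert normalize_variant(seq, 3, "TT", "T") == \
            normalize_variant(seq, 4, "TT", "T") == \
            normalize_variant(seq, 5, "TT", "T")

    def test_leading_common_base_trimmed(self):
        assert normalize_variant("ACGTACGT", 2, "GT", "GA") == (3, "T", "A")


def make_benchmark():
    donor = Assembly({"chr1": "ACGT" * 25_000})  # 100 kb
    bench = [
        GenotypedVariant("chr1", 1_000, "C", ("T",), (1, 1)),   # hom
        GenotypedVariant("chr1", 2_000, "A", ("G",), (0, 1)),   # het
        GenotypedVariant("chr1", 3_000, "A", ("G",), (1, 1)),
    ]
    regions = [("chr1", 0, 50_000)]
    return donor, bench, regions


class TestCompare:
    def test_hom_alt_call_matching_benchmark_is_tp(self):
        donor, bench, regions = make_benchmark()
        calls = [GenotypedVariant("chr1", 1_000, "C", ("T",), (1,))]
        cmp_ = compare_small_variants(calls, bench, regions, donor)
        assert len(cmp_.tps) == 1 and len(cmp_.fps) == 0
        assert len(cmp_.fns) == 2

    def test_call_outside_regions_ignored(self):
        donor, bench, regions = make_benchmark()
        calls = [GenotypedVariant("chr1", 60_000, "A", ("G",), (1,))]
        cmp_ = compare_small_variants(calls, bench, regions, donor)
        assert cmp_.tps == [] and cmp_.fps == []

    def test_het_benchmark_with_hom_call_is_genotype_fp(self):
        donor, bench, regions = make_benchmark()
        calls = [GenotypedVariant("chr1", 2_000, "A", ("G",), (1,))]
        cmp_ = compare_small_variants(calls, bench, regions, donor)
        assert cmp_.tps == []
        assert len(cmp_.fps) == 1
        assert cmp_.fps[0].info["BENCH_GT"] == (0, 1)
        modified, counts = modified_fp_filter(cmp_.fps, bench, [])
        assert counts["gt"] == 1 and modified == []

    def test_region_size_is_summed_bed_length(self):
        donor, bench, regions = make_benchmark()
        cmp_ = compare_small_variants([], bench, regions, donor)
        assert cmp_.region_size == 50_000


class TestModifiedFpFilter:
    def test_proximity_boundary_at_30bp(self):
        donor, bench, regions = make_benchmark()
        near = GenotypedVariant("chr1", 1_029, "A", ("T",), (1,))   # 29 bp away
        far = GenotypedVariant("chr1", 1_031, "A", ("T",), (1,))    # 31 bp away
        exact = GenotypedVariant("chr1", 1_030, "A", ("T",), (1,))  # 30 bp away
        modified, counts = modified_fp_filter([near, far, exact], bench, [])
        assert counts["al"] == 2          # 29 and 30 are excluded, 31 is not
        assert [f.pos for f in modified] == [1_031]

    def test_excluded_region_bucket(self):
        donor, bench, regions = make_benchmark()
        fp = GenotypedVariant("chr1", 10_000, "A", ("T",), (1,))
        modified, counts = modified_fp_filter([fp], bench,
                                              [("chr1", 5_000, 17_000)])
        assert counts["region"] == 1 and modified == []

    def test_precedence_gt_over_al_over_region(self):
        donor, bench, regions = make_benchmark()
        fp = GenotypedVariant("chr1", 2_000, "A", ("G",), (1,),
                              info={"BENCH_GT": (0, 1)})
        _, counts = modified_fp_filter([fp], bench, [("chr1", 0, 50_000)])
        assert counts == {"gt": 1, "al": 0, "region": 0, "modified": 0,
                          "buckets": counts["buckets"]}

    def test_partition_is_exact(self):
        donor, bench, regions = make_benchmark()
        fps = [GenotypedVariant("chr1", p, "A", ("T",), (1,))
               for p in (1_010, 6_000, 40_000, 41_000)]
        modified, counts = modified_fp_filter(fps, bench, [("chr1", 5_000, 17_000)])
        assert counts["gt"] + counts["al"] + counts["region"] + \
            counts["modified"] == len(fps)


class TestQv:
    @pytest.mark.parametrize("fp,size,expected", [
        (1, 10**6, 60.0),
        (10, 10**6, 50.0),
        (79_269, 2_542_560_893, 45.06),   # plausible genome-scale figures
    ])
    def test_closed_form(self, fp, size, expected):
        qv, capped = compute_qv(fp, size)
        assert not capped
        assert qv == pytest.approx(-10 * math.log10(fp / size), abs=1e-9)
        assert qv == pytest.approx(expected, abs=0.01)

    def test_zero_fp_returns_cap_with_flag(self):
        qv, capped = compute_qv(0, 10**6)
        assert qv == 90.0 and capped

    def test_monotonicity_and_doubling_rule(self):
        qv1, _ = compute_qv(10, 10**6)
        qv2, _ = compute_qv(20, 10**6)
        qv3, _ = compute_qv(10, 2 * 10**6)
        assert qv2 < qv1 < qv3
        assert qv3 - qv1 == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_qv(1, 0)
        with pytest.raises(ValueError):
            compute_qv(-1, 100)


class TestCorrections:
    def test_single_substitution_changes_one_base(self, rng):
        seq = random_seq(rng, 1_000)
        asm = Assembly({"c": seq})
        fp = GenotypedVariant("chr1", 500, "A", (seq[500],), (1,),
                              info={"ASM_CHROM": "c", "ASM_POS": 500})
        # donor truth says base should be A; assembly has seq[500]
        fp = GenotypedVariant("chr1", 500, "A" if seq[500] != "A" else "C",
                              (seq[500],), (1,),
                              info={"ASM_CHROM": "c", "ASM_POS": 500})
        out, applied = apply_corrections(asm, plan_corrections([fp]))
        diffs = [i for i in range(1_000) if out["c"][i] != seq[i]]
        assert diffs == [500]
        assert out["c"][500] == fp.ref

    def test_insertion_and_deletion_errors_reverted(self, rng):
        seq = random_seq(rng, 1_000)
        # assembly inserted "GGG" at 300 and dropped 2 bases at 600
        asm_seq = seq[:300] + "GGG" + seq[300:600] + seq[602:]
        asm = Assembly({"c": asm_seq})
        ins_fp = GenotypedVariant("chr1", 299, seq[299], (seq[299] + "GGG",),
                                  (1,), info={"ASM_CHROM": "c", "ASM_POS": 300,
                                              "ASM_LEN": 3})
        del_fp = GenotypedVariant("chr1", 599, seq[599:602], (seq[599],),
                                  (1,), info={"ASM_CHROM": "c",
                                              "ASM_POS": 603,  # post-insertion coords
                                              "ASM_LEN": 2})
        out, applied = apply_corrections(asm, plan_corrections([ins_fp, del_fp]))
        assert len(applied) == 2
        assert out["c"] == seq

    def test_corrections_reduce_modified_fp_on_synthetic_data(self, ds_medium):
        from refcurate.scaffold import tile
        ds = ds_medium
        t = ds.truth
        chroms, plan, _, _ = tile(ds.contigs, ds.reference, ds.coverage)
        calls = call_small_variants(chroms, ds.reference)
        res, modified = benchmark_assembly(calls, t.variants,
                                           t.benchmark_regions,
                                           t.excluded_regions, ds.reference)
        assert res.fp_modified > 0
        out, applied = apply_corrections(chroms, plan_corrections(modified))
        calls2 = call_small_variants(out, ds.reference)
        res2, _ = benchmark_assembly(calls2, t.variants, t.benchmark_regions,
                                     t.excluded_regions, ds.reference)
        assert res2.fp_modified < res.fp_modified


class TestCaller:
    def test_planted_differences_called_exactly(self, rng):
        donor_seq = random_seq(rng, 50_000)
        donor = Assembly({"chr1": donor_seq})
        sample = list(donor_seq)
        sample[10_000] = {"A": "G", "C": "T", "G": "A", "T": "C"}[sample[10_000]]
        sample = "".join(sample)
        sample = sample[:20_000] + sample[20_003:]          # 3 bp deletion
        sample = sample[:30_000] + "ACGTA" + sample[30_000:]  # 5 bp insertion
        calls = call_small_variants(Assembly({"s": sample}), donor)
        snvs = [c for c in calls if c.is_snv]
        assert [(c.pos, c.ref) for c in snvs] == [(10_000, donor_seq[10_000])]
        # deletion called as one anchored event at the deleted span
        dels = [c for c in calls if len(c.ref) > len(c.alts[0])]
        assert len(dels) == 1 and dels[0].pos == 19_999
        assert len(dels[0].ref) - 1 == 3
        # the optimal path may fragment an insertion into cost-equal pieces;
        # the net inserted length is what must be conserved
        ins = [c for c in calls if len(c.ref) < len(c.alts[0])]
        assert all(abs(c.pos - 30_000) < 10 for c in ins)
        assert sum(len(c.alts[0]) - 1 for c in ins) == 5


@pytest.fixture(scope="module")
def sv_world():
    rng = np.random.default_rng(7)
    donor_seq = random_seq(rng, 120_000)
    donor = Assembly({"chr1": donor_seq})
    ins_seq = random_seq(rng, 120)
    svs = [
        # hom insertion at 20 kb, present in the assembly
        GenotypedVariant("chr1", 20_000, donor_seq[20_000],
                         (donor_seq[20_000] + ins_seq,), (1, 1),
                         info={"SVTYPE": "INS", "SVLEN": 120}),
        # hom deletion at 50 kb, present in the assembly
        GenotypedVariant("chr1", 50_000, donor_seq[50_000:50_201],
                         (donor_seq[50_000],), (1, 1),
                         info={"SVTYPE": "DEL", "SVLEN": -200}),
        # het deletion at 80 kb, NOT applied to the assembly
        GenotypedVariant("chr1", 80_000, donor_seq[80_000:80_151],
                         (donor_seq[80_000],), (0, 1),
                         info={"SVTYPE": "DEL", "SVLEN": -150}),
    ]
    asm = donor_seq[:20_001] + ins_seq + donor_seq[20_001:50_001] + \
        donor_seq[50_201:]
    return donor, Assembly({"asm": asm}), svs


class TestSvPresence:
    def test_applied_svs_present_unapplied_absent(self, sv_world):
        donor, asm, svs = sv_world
        status = sv_presence(svs, asm, donor)
        assert [s.status for s in status] == ["present", "present", "absent"]

    def test_absent_deletion_shows_length_discrepancy(self, sv_world):
        donor, asm, svs = sv_world
        status = sv_presence(svs, asm, donor)
        assert status[2].span_delta is not None
        assert status[2].span_delta >= 140

    def test_assay_on_consensus_haplotype(self, ds_medium):
        """Hom truth SVs are present in a haploid assembly of haplotype 1;
        het SVs are present iff haplotype 1 carries them."""
        t = ds_medium.truth
        index = KmerIndex(t.consensus)
        status = sv_presence(t.svs, index, ds_medium.reference)
        by_key = {(s.chrom, s.pos): s for s in status}
        for v in t.svs:
            s = by_key[(v.chrom, v.pos)]
            if s.status == "ambiguous":
                continue
            if set(v.genotype) == {1}:
                assert s.status == "present"
            elif v.genotype[0] == 1:
                assert s.status == "present"
            else:
                assert s.status == "absent"
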