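from collections import Counter

import numpy as np
import pytest

from refcurate import annotqc
from refcurate.annotqc import (ConsequenceRecord, classify_all,
                               classify_consequence, detect_translocations,
                               gene_disruption_summary, paralog_presence,
                               score_transcript_mappings)
from refcurate.model import Assembly
from refcurate.transcripts import TranscriptSeq, build_gene_models, \
    extract_transcript_sequences


def tx(tid, gid, chrom, mrna, cds=""):
    return TranscriptSeq(tid, gid, chrom, "+", mrna, cds)


class TestMappingScores:
    def test_identical_transcript_fully_mapped(self):
        src = {"t1": tx("t1", "g1", "chr1", "ATGCCCGGGTAA")}
        tgt = {"t1": tx("t1", "g1", "asm1", "ATGCCCGGGTAA")}
        (m,) = score_transcript_mappings(src, tgt)
        assert (m.coverage, m.identity, m.status) == (100.0, 100.0, "mapped")

    def test_forty_percent_target_is_partial(self):
        mrna = "ATGC" * 25
        src = {"t1": tx("t1", "g1", "chr1", mrna)}
        tgt = {"t1": tx("t1", "g1", "asm1", mrna[:40])}
        (m,) = score_transcript_mappings(src, tgt)
        assert m.status == "partial"
        assert m.coverage == pytest.approx(40.0, abs=1.0)

    def test_exactly_half_coverage_counts_as_mapped(self):
        mrna = "ATGC" * 25
        src = {"t1": tx("t1", "g1", "chr1", mrna)}
        tgt = {"t1": tx("t1", "g1", "asm1", mrna[:50])}
        (m,) = score_transcript_mappings(src, tgt)
        assert m.status == "mapped"

    def test_absent_transcript_unmapped(self):
        src = {"t1": tx("t1", "g1", "chr1", "ATGCCCGGGTAA")}
        (m,) = score_transcript_mappings(src, {})
        assert m.status == "unmapped" and m.target_chrom is None


CDS = ("ATG" + "GCA TCC GAT CAT GAA TTC TGG AAA CTT CGC".replace(" ", "")
       + "TAA")


class TestClassifyConsequence:
    def test_identical_nucleotides(self):
        assert classify_consequence(CDS, CDS).category == "identical"

    def test_synonymous_change_is_protein_identical(self):
        # GCA -> GCG, still alanine
        mutated = CDS.replace("GCA", "GCG", 1)
        assert classify_consequence(CDS, mutated).category == "identical"

    def test_missense(self):
        mutated = CDS.replace("GCA", "CCA", 1)  # Ala -> Pro
        assert classify_consequence(CDS, mutated).category == "missense"

    def test_inframe_deletion_and_insertion(self):
        assert classify_consequence(CDS, CDS[:6] + CDS[9:]).category == \
            "inframe_deletion"
        assert classify_consequence(CDS, CDS[:6] + "AAA" + CDS[6:]).category == \
            "inframe_insertion"

    def test_single_base_deletion_is_frameshift(self):
        assert classify_consequence(CDS, CDS[:10] + CDS[11:]).category == \
            "frameshift"

    def test_start_codon_change_is_start_lost(self):
        assert classify_consequence(CDS, "ATA" + CDS[3:]).category == \
            "start_lost"

    def test_internal_stop_is_stop_gained(self):
        mutated = CDS[:9] + "TAA" + CDS[12:]
        assert classify_consequence(CDS, mutated).category == "stop_gained"

    def test_terminal_stop_change_is_stop_lost(self):
        assert classify_consequence(CDS, CDS[:-3] + "CAA").category == \
            "stop_lost"

    def test_stop_gained_outranks_missense(self):
        # both a missense change and a premature stop: report the stop
        mutated = (CDS.replace("GCA", "CCA", 1))[:12] + "TAA" + CDS[15:]
        assert classify_consequence(CDS, mutated).category == "stop_gained"

    def test_partial_mapping_is_truncated_and_missing_is_unmapped(self):
        assert classify_consequence(CDS, CDS[:30], "partial").category == \
            "truncated"
        assert classify_consequence(CDS, None, "unmapped").category == \
            "unmapped"


class TestOracleAgreement:
    """The alignment-based classifier must agree with a brute-force
    codon-walk oracle on randomized CDS pairs (one mutation per pair)."""

    STOPS = {"TAA", "TAG", "TGA"}

    def _oracle(self, src, tgt):
        # independent translate-and-diff, no alignment machinery
        table = {}
        from Bio.Data.CodonTable import standard_dna_table
        table = dict(standard_dna_table.forward_table)

        def aa(codon):
            return "*" if codon in self.STOPS else table.get(codon, "X")

        def protein(cds):
            return [aa(cds[i:i + 3]) for i in range(0, len(cds) - 2, 3)]

        if (len(tgt) - len(src)) % 3 != 0:
            return "frameshift"
        p_s, p_t = protein(src), protein(tgt)
        if "*" in p_t[:-1]:
            return "stop_gained"
        if p_s[-1] == "*" and p_t[-1] != "*":
            return "stop_lost"
        if tgt[:3] != "ATG" and src[:3] == "ATG":
            return "start_lost"
        if len(tgt) > len(src):
            return "inframe_insertion"
        if len(tgt) < len(src):
            return "inframe_deletion"
        if p_t != p_s:
            return "missense"
        return "identical"

    def _random_pair(self, rng):
        from refcurate.simulate import _codon_seq
        src = _codon_seq(rng, int(rng.integers(20, 120)))
        kind = rng.integers(6)
        s = list(src)
        if kind == 0:            # substitution somewhere
            p = int(rng.integers(len(s)))
            s[p] = "ACGT"[int(rng.integers(4))]
        elif kind == 1:          # small deletion
            L = int(rng.integers(1, 7))
            p = int(rng.integers(len(s) - L))
            del s[p:p + L]
        elif kind == 2:          # small insertion
            L = int(rng.integers(1, 7))
            p = int(rng.integers(len(s)))
            ins = [str(c) for c in
                   np.array(list("ACGT"))[rng.integers(0, 4, size=L)]]
            s[p:p] = ins
        elif kind == 3:          # force premature stop
            codon = int(rng.integers(1, len(s) // 3 - 1))
            s[codon * 3:codon * 3 + 3] = list("TAA")
        elif kind == 4:          # break the start codon
            s[int(rng.integers(3))] = "C"
        else:                    # break the stop codon
            s[-1] = "C"
        return src, "".join(s)

    def test_thousand_randomized_pairs_agree(self):
        rng = np.random.default_rng(77)
        mismatches = []
        for _ in range(1_000):
            src, tgt = self._random_pair(rng)
            got = classify_consequence(src, tgt).category
            want = self._oracle(src, tgt)
            if got != want:
                mismatches.append((src, tgt, got, want))
        assert mismatches == []


class TestGeneDisruption:
    def _world(self, cats):
        src = {f"t{i}": tx(f"t{i}", "g1", "chr1", "A" * 30)
               for i in range(len(cats))}
        cons = {f"t{i}": ConsequenceRecord(f"t{i}", c)
                for i, c in enumerate(cats)}
        return gene_disruption_summary(cons, src)

    def test_one_intact_isoform_rescues_the_gene(self):
        assert self._world(["frameshift", "identical"])["g1"] == \
            "intact-with-affected-isoforms"

    def test_all_isoforms_disrupted_means_disrupted(self):
        assert self._world(["frameshift", "stop_gained"])["g1"] == "disrupted"

    def test_missense_is_not_disrupting(self):
        assert self._world(["missense", "identical"])["g1"] == "intact"


class TestTranslocationsAndParalogs:
    def test_no_translocations_on_matching_chromosomes(self, ds_small):
        from refcurate.annotqc import TranslocatedGene
        t = ds_small.truth
        src_feats = [f for f in t.annotation]
        src = extract_transcript_sequences(ds_small.reference, src_feats)
        maps = score_transcript_mappings(src, src)  # identity transfer
        moved = detect_translocations(
            maps, build_gene_models(src_feats), build_gene_models(src_feats),
            {n: ds_small.reference.length(n) for n in ds_small.reference.names()},
            {n: ds_small.reference.length(n) for n in ds_small.reference.names()})
        assert moved == []

    def test_reciprocal_exchange_detected_with_subtelomere_flag(self, ds_small):
        t = ds_small.truth
        src = extract_transcript_sequences(ds_small.reference, t.annotation)
        tgt = extract_transcript_sequences(t.consensus, t.projected_annotation)
        maps = score_transcript_mappings(src, tgt)
        moved = detect_translocations(
            maps, build_gene_models(t.annotation),
            build_gene_models(t.projected_annotation),
            {n: ds_small.reference.length(n) for n in ds_small.reference.names()},
            {n: t.consensus.length(n) for n in t.consensus.names()})
        assert moved  # the planted exchange carries at least one gene
        pairs = {(g.source_chrom, g.target_chrom) for g in moved}
        tr = t.translocations[0]
        assert pairs <= {(tr.chrom_a, tr.chrom_b), (tr.chrom_b, tr.chrom_a)}
        assert all(g.subtelomeric for g in moved)

    def test_gene_with_isoforms_on_two_chromosomes_flagged(self):
        from refcurate.annotqc import TranscriptMapping
        from refcurate.transcripts import GeneModel
        maps = [TranscriptMapping("t1", "g1", "chr1", "chr2", 100, 100, "mapped"),
                TranscriptMapping("t2", "g1", "chr1", "chr3", 100, 100, "mapped")]
        genes = {"g1": GeneModel("g1", "chr1", "+", 100, 200)}
        moved = detect_translocations(maps, genes, {}, {"chr1": 10_000}, {})
        assert len(moved) == 1 and moved[0].conflict

    def test_deleted_gene_with_planted_paralog_found(self, ds_small):
        t = ds_small.truth
        genes = build_gene_models(t.annotation)
        assert t.deleted_genes
        seqs = {gid: ds_small.reference[genes[gid].chrom]
                [genes[gid].start:genes[gid].end] for gid in t.deleted_genes}
        hits = paralog_presence(seqs, t.consensus)
        for h in hits:
            assert h.present and h.identity >= 97.0

    def test_gene_without_homolog_has_no_hit(self, rng):
        target = Assembly({"a": "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=50_000)])})
        gene = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1_500)])
        (hit,) = paralog_presence({"gX": gene}, target)
        assert not hit.present


class TestEndToEndRecovery:
    def test_truth_consequence_labels_recovered(self, ds_small):
        """The classifier recovers every generator truth label through the
        full extract -> align -> classify route."""
        t = ds_small.truth
        src = extract_transcript_sequences(ds_small.reference, t.annotation)
        tgt = extract_transcript_sequences(t.consensus, t.projected_annotation)
        maps = score_transcript_mappings(src, tgt)
        cons = classify_all(src, tgt, maps)
        got = {tid: rec.category for tid, rec in cons.items()}
        assert got == t.consequences

    def test_category_counts_partition_transcripts(self, ds_small):
        t = ds_small.truth
        src = extract_transcript_sequences(ds_small.reference, t.annotation)
        tgt = extract_transcript_sequences(t.consensus, t.projected_annotation)
        maps = score_transcript_mappings(src, tgt)
        cons = classify_all(src, tgt, maps)
        counts = Counter(r.category for r in cons.values())
        assert sum(counts.values()) == len(src)
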