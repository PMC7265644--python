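"""Annotation-transfer quality control.

Given the same gene set annotated on a source and a target genome (the
transfer itself is produced upstream, e.g. by a liftover mapper or the
synthetic projector), this module scores each transcript's mRNA
coverage/identity, flags genes that moved between chromosomes, classifies
the protein-level consequence of every coding change, summarizes gene-level
disruption, and checks whether genes missing from the target still have a
family member present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import KmerIndex, anchor_align, best_record, global_align, locate_infix
from .model import Assembly
from .simulate import CONSEQUENCE_PRECEDENCE
from .transcripts import GeneModel, TranscriptSeq

log = logging.getLogger(__name__)

MAPPED_COVERAGE = 50.0   # % of the source mRNA that must be recovered

DISRUPTING = {"frameshift", "stop_gained", "stop_lost", "start_lost",
              "truncated", "unmapped"}


@dataclass
class TranscriptMapping:
    transcript_id: str
    gene_id: str
    source_chrom: str
    target_chrom: str | None
    coverage: float   # percent of source mRNA aligned
    identity: float   # percent identity of the mRNA alignment
    status: str       # "mapped" | "partial" | "unmapped"


@dataclass
class ConsequenceRecord:
    transcript_id: str
    category: str
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transcript mapping scores
# ---------------------------------------------------------------------------

def score_transcript_mappings(source: dict[str, TranscriptSeq],
                              target: dict[str, TranscriptSeq],
                              ) -> list[TranscriptMapping]:
    """Coverage/identity per transcript from global mRNA alignment.

    A transcript is *mapped* when at least half of its source mRNA is
    recovered in the target, *partial* below that, *unmapped* when the
    target annotation has no placement at all.
    """
    out = []
    for tid, src in sorted(source.items()):
        tgt = target.get(tid)
        if tgt is None or not tgt.mrna:
            out.append(TranscriptMapping(tid, src.gene_id, src.chrom, None,
                                         0.0, 0.0, "unmapped"))
            continue
        ga = global_align(src.mrna, tgt.mrna)
        status = "mapped" if ga.coverage >= MAPPED_COVERAGE else "partial"
        out.append(TranscriptMapping(tid, src.gene_id, src.chrom, tgt.chrom,
                                     round(ga.coverage, 3),
                                     round(ga.identity, 3), status))
    return out


# ---------------------------------------------------------------------------
# translocated genes
# ---------------------------------------------------------------------------

@dataclass
class TranslocatedGene:
    gene_id: str
    source_chrom: str
    target_chrom: str
    block: int
    subtelomeric: bool
    conflict: bool = False   # isoforms landed on more than one chromosome


def detect_translocations(mappings: list[TranscriptMapping],
                          source_genes: dict[str, GeneModel],
                          target_genes: dict[str, GeneModel],
                          source_lengths: dict[str, int],
                          target_lengths: dict[str, int],
                          subtelomere_fraction: float = 0.01,
                          subtelomere_min: int = 5_000,
                          chrom_name_map: dict[str, str] | None = None,
                          ) -> list[TranslocatedGene]:
    """Genes whose mapped isoforms land on a different chromosome.

    Adjacent translocated genes (source order) with the same source/target
    chromosome pair merge into one block.  A gene is flagged subtelomeric
    when either endpoint of the move lies within the terminal
    ``subtelomere_fraction`` of its chromosome (with an absolute floor of
    ``subtelomere_min`` bases — subtelomeres do not shrink with assembly
    size).
    """
    chrom_name_map = chrom_name_map or {}
    per_gene: dict[str, set[str]] = {}
    for m in mappings:
        if m.status == "mapped" and m.target_chrom is not None:
            per_gene.setdefault(m.gene_id, set()).add(m.target_chrom)
    moved = []
    for gid, chroms in per_gene.items():
        src = source_genes.get(gid)
        if src is None:
            continue
        expected = chrom_name_map.get(src.chrom, src.chrom)
        others = {c for c in chroms if c != expected}
        if not others:
            continue
        target_chrom = sorted(others)[0]

        def near_end(pos, length):
            margin = max(int(length * subtelomere_fraction), subtelomere_min)
            return pos <= margin or pos >= length - margin

        tgt = target_genes.get(gid)
        sub = near_end((src.start + src.end) // 2, source_lengths[src.chrom])
        if tgt is not None and tgt.chrom in target_lengths:
            sub = sub or near_end((tgt.start + tgt.end) // 2,
                                  target_lengths[tgt.chrom])
        moved.append(TranslocatedGene(gid, src.chrom, target_chrom, -1, sub,
                                      conflict=len(chroms) > 1))
    moved.sort(key=lambda g: (g.source_chrom,
                              source_genes[g.gene_id].start))
    block = 0
    prev = None
    for g in moved:
        pair = (g.source_chrom, g.target_chrom)
        if pair != prev:
            block += 1
        g.block = block
        prev = pair
    return moved


# ---------------------------------------------------------------------------
# protein-consequence classification
# ---------------------------------------------------------------------------

def _translate(cds: str) -> str:
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


def classify_consequence(source_cds: str, target_cds: str | None,
                         status: str = "mapped") -> ConsequenceRecord:
    """Protein-level category of a source->target CDS change.

    The nucleotide alignment supplies the edit script; the most
    consequential applicable category wins (a missense change plus a
    premature stop is reported as *stop gained*, etc.).  Frameshift is
    judged on the net CDS length change mod 3, so a compensating indel
    pair downstream reads as in-frame with an altered stretch.  Start-loss
    means the target CDS no longer begins with ATG; alternative start
    codons are not honored.
    """
    tid_details: dict = {}
    if status == "unmapped" or target_cds is None or not target_cds:
        return ConsequenceRecord("", "unmapped")
    if status == "partial":
        return ConsequenceRecord("", "truncated")
    src, tgt = source_cds.upper(), target_cds.upper()
    if src == tgt:
        return ConsequenceRecord("", "identical")
    ga = global_align(src, tgt)
    indels = [(n, op) for n, op in ga.edit_script if op in "ID"]
    tid_details = {"edit_distance": ga.edit_distance,
                   "indels": len(indels),
                   "net": len(tgt) - len(src)}
    flags = set()
    if (len(tgt) - len(src)) % 3 != 0:
        flags.add("frameshift")
    prot_t = _translate(tgt)
    prot_s = _translate(src)
    if tgt[:3] != "ATG" and src[:3] == "ATG":
        flags.add("start_lost")
    if "*" in prot_t[:-1]:
        flags.add("stop_gained")
    if prot_s.endswith("*") and not prot_t.endswith("*"):
        flags.add("stop_lost")
    if not flags:
        if len(tgt) > len(src):
            flags.add("inframe_insertion")
        elif len(tgt) < len(src):
            flags.add("inframe_deletion")
        elif prot_t != prot_s:
            flags.add("missense")
    if not flags:
        return ConsequenceRecord("", "identical", tid_details)
    for cat in CONSEQUENCE_PRECEDENCE:
        if cat in flags:
            return ConsequenceRecord("", cat, tid_details)
    return ConsequenceRecord("", "identical", tid_details)


def classify_all(source: dict[str, TranscriptSeq],
                 target: dict[str, TranscriptSeq],
                 mappings: list[TranscriptMapping],
                 ) -> dict[str, ConsequenceRecord]:
    status_by_tid = {m.transcript_id: m.status for m in mappings}
    out = {}
    for tid, src in sorted(source.items()):
        status = status_by_tid.get(tid, "unmapped")
        tgt = target.get(tid)
        rec = classify_consequence(src.cds, tgt.cds if tgt else None, status)
        rec.transcript_id = tid
        out[tid] = rec
    return out


# ---------------------------------------------------------------------------
# gene-level disruption
# ---------------------------------------------------------------------------

def gene_disruption_summary(consequences: dict[str, ConsequenceRecord],
                            source: dict[str, TranscriptSeq],
                            ) -> dict[str, str]:
    """Per-gene status: ``disrupted`` only when *every* isoform is disrupted.

    Genes with some but not all isoforms disrupted are
    ``intact-with-affected-isoforms``; the rest are ``intact``.
    """
    by_gene: dict[str, list[str]] = {}
    for tid, rec in consequences.items():
        gid = source[tid].gene_id
        by_gene.setdefault(gid, []).append(rec.category)
    out = {}
    for gid, cats in by_gene.items():
        dis = [c in DISRUPTING for c in cats]
        if all(dis):
            out[gid] = "disrupted"
        elif any(dis):
            out[gid] = "intact-with-affected-isoforms"
        else:
            out[gid] = "intact"
    return out


# ---------------------------------------------------------------------------
# paralog presence for unmapped genes
# ---------------------------------------------------------------------------

@dataclass
class ParalogHit:
    gene_id: str
    present: bool
    identity: float
    target_chrom: str | None = None
    target_start: int | None = None
    target_end: int | None = None


def paralog_presence(gene_sequences: dict[str, str],
                     target: Assembly | KmerIndex,
                     min_identity: float = 90.0) -> list[ParalogHit]:
    """Best-hit search for genes missing from the target.

    Each gene's source genomic sequence is anchor-aligned to the target;
    the best chain is re-scored with a global alignment of the hit slice.
    A family member is *present* when that identity reaches
    ``min_identity`` percent.
    """
    index = target if isinstance(target, KmerIndex) else KmerIndex(target)
    out = []
    for gid, seq in sorted(gene_sequences.items()):
        recs = anchor_align(seq, index, refine=True)
        best = best_record(recs)
        if best is None:
            out.append(ParalogHit(gid, False, 0.0))
            continue
        tseq = index.target[best.target_name]
        pad = 100
        s = max(0, best.target_start - pad)
        e = min(len(tseq), best.target_end + pad)
        ts, te, dist = locate_infix(seq.upper(), tseq[s:e].upper())
        cols = max(len(seq), te - ts)
        ident = 100.0 * (cols - dist) / cols
        out.append(ParalogHit(gid, ident >= min_identity, round(ident, 3),
                              best.target_name, best.target_start,
                              best.target_end))
    return out
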