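"""Transcript sequence extraction from an assembly + GFF3 annotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import GffFeature
from .model import Assembly, revcomp

log = logging.getLogger(__name__)


@dataclass
class TranscriptSeq:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    mrna: str
    cds: str
    flagged: bool = False  # CDS length not phase-consistent


@dataclass
class GeneModel:
    """A gene with its transcripts, rebuilt from flat GFF3 features."""
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, dict] = field(default_factory=dict)


def build_gene_models(features: list[GffFeature]) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    tx_to_gene: dict[str, str] = {}
    for ft in features:
        if ft.type == "gene":
            genes[ft.id] = GeneModel(ft.id, ft.seqid, ft.strand, ft.start, ft.end)
    for ft in features:
        if ft.type in ("mRNA", "transcript"):
            gid = ft.parent
            if gid not in genes:
                genes[gid] = GeneModel(gid, ft.seqid, ft.strand, ft.start, ft.end)
            genes[gid].transcripts[ft.id] = {"exons": [], "cds": [],
                                             "chrom": ft.seqid, "strand": ft.strand}
            tx_to_gene[ft.id] = gid
    for ft in features:
        if ft.type in ("exon", "CDS"):
            tid = ft.parent
            gid = tx_to_gene.get(tid)
            if gid is None:
                continue
            key = "exons" if ft.type == "exon" else "cds"
            genes[gid].transcripts[tid][key].append((ft.start, ft.end))
    for g in genes.values():
        for tx in g.transcripts.values():
            tx["exons"].sort()
            tx["cds"].sort()
    return genes


def extract_transcript_sequences(assembly: Assembly,
                                 features: list[GffFeature]) -> dict[str, TranscriptSeq]:
    """mRNA and CDS sequence per transcript.

    Minus-strand transcripts are reverse-complemented; CDS segments are
    concatenated in translation order.  A CDS whose length is not a
    multiple of 3 is flagged (and logged) rather than rejected.
    """
    out: dict[str, TranscriptSeq] = {}
    genes = build_gene_models(features)
    for gid, gene in sorted(genes.items()):
        for tid, tx in sorted(gene.transcripts.items()):
            chrom, strand = tx["chrom"], tx["strand"]
            seq = assembly[chrom]
            exons = tx["exons"] or tx["cds"]
            mrna = "".join(seq[s:e] for s, e in exons)
            cds = "".join(seq[s:e] for s, e in tx["cds"])
            if strand == "-":
                mrna = revcomp(mrna)
                cds = revcomp(cds)
            flagged = bool(cds) and len(cds) % 3 != 0
            if flagged:
                log.warning("transcript %s: CDS length %d not a multiple of 3",
                            tid, len(cds))
            out[tid] = TranscriptSeq(tid, gid, chrom, strand, mrna.upper(),
                                     cds.upper(), flagged)
    return out
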