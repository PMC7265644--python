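"""Reference-guided tiling: contigs -> ordered, oriented chromosomes.

Stages: filter haplotype-duplicate contigs, align contigs to the donor,
flag alignment breakpoints interior to a contig, confirm them against read
coverage (low <= ``low`` or high > ``high`` within ``window`` of the
breakpoint), split confirmed mis-assemblies, then order and orient the
pieces along each donor chromosome with estimated N gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import KmerIndex, anchor_align
from .model import (AlignmentRecord, Assembly, CoverageTrack, TilingGap,
                    TilingPlan, TilingSegment, revcomp)

log = logging.getLogger(__name__)

# suppress repeat-induced micro-hits when assigning/ordering contigs
MIN_ALIGNMENT_LENGTH = 2_000
# alignment ends from adjacent chunks jitter; candidates within this radius merge
MERGE_RADIUS = 1_000


# ---------------------------------------------------------------------------
# contig-to-donor alignment
# ---------------------------------------------------------------------------

def align_contigs(contigs: Assembly, donor: Assembly | KmerIndex,
                  k: int = 21) -> dict[str, list[AlignmentRecord]]:
    """Anchor-align every contig to the donor; records grouped per contig."""
    index = donor if isinstance(donor, KmerIndex) else KmerIndex(donor, k)
    out = {}
    for name in contigs.names():
        out[name] = anchor_align(contigs[name], index, query_name=name)
    return out


def self_align(contigs: Assembly, k: int = 21,
               sample_step: int = 64) -> dict[str, list[AlignmentRecord]]:
    """All-vs-larger self alignments for duplicate filtering.

    Candidate partners are prescreened with a sparse k-mer multimap
    (indexed every ``sample_step`` bases, queried densely so offset phase
    cannot hide a duplicate); each candidate pair is then anchor-aligned
    with uniqueness assessed within the pair only (duplicated sequence is
    by definition not unique genome-wide).
    """
    multimap: dict[str, list[str]] = {}
    for name in contigs.names():
        seq = contigs[name].upper()
        for i in range(0, len(seq) - k + 1, sample_step):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                lst = multimap.setdefault(kmer, [])
                if len(lst) < 8:
                    lst.append(name)
    index_cache: dict[str, KmerIndex] = {}
    out: dict[str, list[AlignmentRecord]] = {c: [] for c in contigs.names()}
    for name in contigs.names():
        seq = contigs[name].upper()
        votes: dict[str, int] = {}
        for q in (seq, revcomp(seq)):
            for i in range(len(q) - k + 1):
                for other in multimap.get(q[i:i + k], ()):
                    if other != name:
                        votes[other] = votes.get(other, 0) + 1
        for other, v in sorted(votes.items()):
            if v < 3 or contigs.length(other) <= contigs.length(name):
                continue
            if other not in index_cache:
                index_cache[other] = KmerIndex(
                    Assembly({other: contigs[other]}, validate=False), k)
            out[name].extend(anchor_align(seq, index_cache[other],
                                          query_name=name, refine=True))
    return out


# ---------------------------------------------------------------------------
# haplotype-duplicate filtering
# ---------------------------------------------------------------------------

def filter_haplotype_duplicates(contigs: Assembly,
                                self_alignments: dict[str, list[AlignmentRecord]],
                                identity_threshold: float = 0.97,
                                coverage_requirement: float = 0.995,
                                ) -> tuple[Assembly, list[dict]]:
    """Drop contigs fully covered by a single larger contig at > threshold identity.

    A contig is removed iff alignments to one larger partner cover at least
    ``coverage_requirement`` of it and their aggregate identity (summed
    matches over covered bases) strictly exceeds ``identity_threshold``.
    The default containment requirement leaves half a percent of slack for
    anchor-end jitter at contig edges.  Returns the kept assembly and a
    removal report (contig, partner, bp).
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    removed: list[dict] = []
    keep = contigs.copy()
    for name in contigs.names():
        by_partner: dict[str, list[AlignmentRecord]] = {}
        for rec in self_alignments.get(name, []):
            if rec.target_name != name:
                by_partner.setdefault(rec.target_name, []).append(rec)
        length = contigs.length(name)
        for partner, recs in sorted(by_partner.items()):
            if contigs.length(partner) <= length:
                continue
            ivs = sorted((r.query_start, r.query_end) for r in recs)
            covered = 0
            prev = 0
            for s, e in ivs:
                covered += max(0, e - max(s, prev))
                prev = max(prev, e)
            if covered < coverage_requirement * length:
                continue
            matches = sum(r.matches for r in recs)
            blocks = sum(r.block_length for r in recs)
            if blocks and matches / blocks > identity_threshold:
                removed.append({"contig": name, "partner": partner,
                                "length": length,
                                "identity": matches / blocks})
                del keep.sequences[name]
                break
    log.info("duplicate filter removed %d contigs (%d bp)",
             len(removed), sum(r["length"] for r in removed))
    return keep, removed


# ---------------------------------------------------------------------------
# chromosome assignment
# ---------------------------------------------------------------------------

def assign_contigs(alignments: dict[str, list[AlignmentRecord]],
                   min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
                   ) -> tuple[dict[str, tuple[str, str]], list[str]]:
    """Assign each contig to (chromosome, strand) by summed aligned bases.

    Ties break to the lexicographically smaller chromosome name; strand by
    majority of aligned bases on the winning chromosome.  Contigs with no
    qualifying alignment are returned as unplaced.
    """
    assignments: dict[str, tuple[str, str]] = {}
    unplaced: list[str] = []
    for contig, recs in alignments.items():
        totals: dict[str, int] = {}
        strand_bases: dict[str, dict[str, int]] = {}
        for r in recs:
            if r.query_span < min_alignment_length:
                continue
            totals[r.target_name] = totals.get(r.target_name, 0) + r.query_span
            sb = strand_bases.setdefault(r.target_name, {"+": 0, "-": 0})
            sb[r.strand] += r.query_span
        if not totals:
            unplaced.append(contig)
            continue
        best = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        sb = strand_bases[best]
        strand = "+" if sb["+"] >= sb["-"] else "-"
        assignments[contig] = (best, strand)
    return assignments, unplaced


# ---------------------------------------------------------------------------
# breakpoint detection and confirmation
# ---------------------------------------------------------------------------

@dataclass
class CandidateBreakpoint:
    contig: str
    position: int
    classification: str = "unconfirmed"  # | "low-coverage" | "high-coverage"
    split_position: int | None = None


def find_candidate_breakpoints(contig: str, contig_length: int,
                               alignments: list[AlignmentRecord],
                               end_distance: int = 5_000,
                               min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
                               merge_radius: int = MERGE_RADIUS,
                               ) -> list[CandidateBreakpoint]:
    """Alignment ends strictly more than ``end_distance`` from both contig ends.

    Nearby ends (within ``merge_radius``) collapse to their median.
    """
    ends = []
    for r in alignments:
        if r.query_name != contig or r.query_span < min_alignment_length:
            continue
        for pos in (r.query_start, r.query_end):
            if pos > end_distance and pos < contig_length - end_distance:
                ends.append(pos)
    ends.sort()
    out = []
    cluster: list[int] = []
    for pos in ends + [None]:
        if pos is not None and (not cluster or pos - cluster[-1] <= merge_radius):
            cluster.append(pos)
        else:
            if cluster:
                out.append(CandidateBreakpoint(contig, cluster[len(cluster) // 2]))
            cluster = [pos] if pos is not None else []
    return out


def classify_breakpoints(candidates: list[CandidateBreakpoint],
                         coverage: CoverageTrack,
                         low: float = 3.0, high: float = 35.0,
                         window: int = 50_000) -> list[CandidateBreakpoint]:
    """Confirm candidates showing anomalous coverage near the breakpoint.

    Low coverage (<= ``low``) anywhere within ``window`` confirms the
    candidate and splits at the weak point (center of the minimum-depth
    trough); otherwise high coverage (> ``high``) confirms it — a likely
    collapsed repeat — and splits at the alignment breakpoint itself.
    """
    out = []
    for cand in candidates:
        start = max(0, cand.position - window)
        end = min(coverage.sequence_length(cand.contig), cand.position + window)
        mind, minpos = coverage.min_depth(cand.contig, start, end)
        maxd = coverage.max_depth(cand.contig, start, end)
        if mind <= low:
            out.append(CandidateBreakpoint(cand.contig, cand.position,
                                           "low-coverage", minpos))
        elif maxd > high:
            out.append(CandidateBreakpoint(cand.contig, cand.position,
                                           "high-coverage", cand.position))
        else:
            out.append(CandidateBreakpoint(cand.contig, cand.position))
    return out


def split_contigs(contigs: Assembly,
                  candidates: list[CandidateBreakpoint],
                  ) -> tuple[Assembly, dict[str, list[str]]]:
    """Split contigs at every confirmed candidate; names suffixed ``.1``, ``.2``...

    The concatenation of the pieces always equals the original contig.
    """
    splits: dict[str, list[int]] = {}
    for cand in candidates:
        if cand.classification != "unconfirmed" and cand.split_position is not None:
            splits.setdefault(cand.contig, []).append(cand.split_position)
    out = Assembly(validate=False)
    rename: dict[str, list[str]] = {}
    for name in contigs.names():
        seq = contigs[name]
        if name not in splits:
            out.sequences[name] = seq
            rename[name] = [name]
            continue
        positions = sorted(set(p for p in splits[name] if 0 < p < len(seq)))
        bounds = [0] + positions + [len(seq)]
        pieces = []
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]), 1):
            piece = f"{name}.{i}"
            out.sequences[piece] = seq[a:b]
            pieces.append(piece)
        rename[name] = pieces
        log.info("split %s at %s", name, positions)
    return out, rename


# ---------------------------------------------------------------------------
# chromosome building
# ---------------------------------------------------------------------------

GAP_FLOOR = 100  # AGP needs a positive gap; matches the 100-N convention


def build_chromosomes(assignments: dict[str, tuple[str, str]],
                      alignments: dict[str, list[AlignmentRecord]],
                      contigs: Assembly,
                      min_alignment_length: int = MIN_ALIGNMENT_LENGTH,
                      ) -> tuple[Assembly, TilingPlan, Assembly]:
    """Order and orient assigned contigs along donor chromosomes.

    Segments sort by donor midpoint; inter-segment gap sizes come from the
    difference of projected donor positions (floored at 100 N).  When two
    projections overlap, the lower-identity segment is trimmed.  Returns
    (chromosome assembly, tiling plan, unplaced assembly).
    """
    per_chrom: dict[str, list[TilingSegment]] = {}
    placed = set()
    for contig, (chrom, strand) in assignments.items():
        recs = [r for r in alignments.get(contig, [])
                if r.target_name == chrom and r.strand == strand
                and r.query_span >= min_alignment_length]
        if not recs:
            continue
        donor_start = min(r.target_start for r in recs)
        donor_end = max(r.target_end for r in recs)
        matches = sum(r.matches for r in recs)
        blocks = sum(r.block_length for r in recs)
        per_chrom.setdefault(chrom, []).append(TilingSegment(
            contig=contig, contig_start=0, contig_end=contigs.length(contig),
            orientation=strand, donor_chrom=chrom,
            donor_start=donor_start, donor_end=donor_end,
            identity=matches / blocks if blocks else 0.0))
        placed.add(contig)

    plan: dict[str, list] = {}
    chrom_seqs: dict[str, str] = {}
    for chrom in sorted(per_chrom):
        segs = sorted(per_chrom[chrom],
                      key=lambda s: ((s.donor_start + s.donor_end) / 2,
                                     s.contig))
        # resolve overlapping donor projections: trim the weaker segment
        for prev, cur in zip(segs, segs[1:]):
            overlap = prev.donor_end - cur.donor_start
            if overlap > 0:
                victim = cur if cur.identity <= prev.identity else prev
                trim = min(overlap, victim.length - 1)
                if victim is cur:
                    cur.donor_start += overlap
                    if cur.orientation == "+":
                        cur.contig_start += trim
                    else:
                        cur.contig_end -= trim
                else:
                    prev.donor_end -= overlap
                    if prev.orientation == "+":
                        prev.contig_end -= trim
                    else:
                        prev.contig_start += trim
        items: list = []
        parts: list[str] = []
        for i, seg in enumerate(segs):
            if i > 0:
                prev = segs[i - 1]
                est = seg.donor_start - prev.donor_end
                gap = TilingGap(size=max(est, GAP_FLOOR), donor_chrom=chrom,
                                donor_start=prev.donor_end,
                                donor_end=seg.donor_start)
                items.append(gap)
                parts.append("N" * gap.size)
            items.append(seg)
            seq = contigs[seg.contig][seg.contig_start:seg.contig_end]
            parts.append(seq if seg.orientation == "+" else revcomp(seq))
        plan[chrom] = items
        chrom_seqs[chrom] = "".join(parts)

    unplaced = Assembly({c: contigs[c] for c in contigs.names()
                         if c not in placed}, validate=False)
    if len(unplaced):
        log.info("%d contigs left unplaced (%d bp)", len(unplaced),
                 unplaced.total_length())
    tiling = TilingPlan(plan)
    tiling.validate()
    return Assembly(chrom_seqs, validate=False), tiling, unplaced


def tile(contigs: Assembly, donor: Assembly, coverage: CoverageTrack,
         low: float = 3.0, high: float = 35.0, window: int = 50_000,
         end_distance: int = 5_000, k: int = 21,
         ) -> tuple[Assembly, TilingPlan, Assembly, list[CandidateBreakpoint]]:
    """Full tiling stage: align, break, confirm, split, re-align, build."""
    index = KmerIndex(donor, k)
    alignments = align_contigs(contigs, index)
    classified: list[CandidateBreakpoint] = []
    for name in contigs.names():
        cands = find_candidate_breakpoints(name, contigs.length(name),
                                           alignments[name], end_distance)
        classified.extend(classify_breakpoints(cands, coverage, low, high, window))
    split, _ = split_contigs(contigs, classified)
    alignments2 = align_contigs(split, index)
    assignments, _ = assign_contigs(alignments2)
    chroms, plan, unplaced = build_chromosomes(assignments, alignments2, split)
    return chroms, plan, unplaced, classified
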