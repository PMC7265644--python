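"""Two-step donor-reference gap filling with provenance.

Step 1 (*spanned* fill): a gap is closed when contiguous donor sequence
spans it with unique flank anchors of at least ``min_flank`` bases at
``min_identity`` on both sides; the N run is replaced by the donor infill,
recorded in lowercase.

Step 2 (*fitted* insertion): for gaps that no contiguous donor sequence
spans (typically because the donor itself is gapped there), donor contigs
whose coordinates fall inside the gap's projected donor interval are
inserted, each framed by 100-N gaps.  The gap count rises by one per
inserted contig but the total gap length shrinks.

Native (uppercase) sequence is never modified; lowercase bp in the output
always equals the sum of bases inserted over the recorded fill events.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .align import KmerIndex, anchor_align, locate_infix
from .model import Assembly, TilingGap, TilingPlan, TilingSegment

log = logging.getLogger(__name__)

FLANK_GAP = 100          # N run left on both sides of a fitted contig
FLANK_WINDOW = 4_000     # assembly sequence examined on each side of a gap
MIN_INSERT = 200         # smallest donor fragment worth inserting


@dataclass
class FillEvent:
    chromosome: str
    gap_start: int            # coordinates at the time of the event
    gap_end: int
    mode: str                 # "spanned" | "fitted"
    donor_chrom: str
    donor_start: int
    donor_end: int
    bases_inserted: int
    left_flank: int = 0       # anchor length, spanned mode
    right_flank: int = 0
    left_identity: float = 0.0
    right_identity: float = 0.0


def _plan_offsets(items: list) -> list[int]:
    """Chromosome coordinate of each plan item, from cumulative lengths."""
    offsets = []
    pos = 0
    for item in items:
        offsets.append(pos)
        pos += item.length if isinstance(item, TilingSegment) else item.size
    return offsets


def _unique_flank(flank: str, index: KmerIndex, min_flank: int,
                  min_identity: float):
    """The single qualifying donor chain for a flank, or None.

    Qualifying = aligned span >= ``min_flank`` at identity >= ``min_identity``;
    more than one qualifying chain means the flank is not unique.
    """
    recs = [r for r in anchor_align(flank, index, refine=True)
            if r.query_span >= min_flank and r.identity >= min_identity]
    if len(recs) != 1:
        return None
    return recs[0]


def fill_spanned_gaps(assembly: Assembly, donor: Assembly, plan: TilingPlan,
                      min_flank: int = 2_000, min_identity: float = 0.99,
                      max_fill: int = 100_000, k: int = 21,
                      ) -> tuple[Assembly, TilingPlan, list[FillEvent]]:
    """Close gaps spanned by contiguous donor sequence with unique 2-kb flanks."""
    index = KmerIndex(donor, k)
    out = assembly.copy()
    new_plan: dict[str, list] = {}
    events: list[FillEvent] = []
    for chrom in plan.chromosomes():
        items = list(plan.plan[chrom])
        new_items: list = []
        # walk with live coordinates (earlier fills shift later gaps)
        seq = out[chrom]
        pos = 0
        for item in items:
            if isinstance(item, TilingSegment):
                new_items.append(item)
                pos += item.length
                continue
            gap_start, gap_end = pos, pos + item.size
            filled = False
            left = seq[max(0, gap_start - FLANK_WINDOW):gap_start]
            right = seq[gap_end:gap_end + FLANK_WINDOW]
            lrec = _unique_flank(left, index, min_flank, min_identity) if left else None
            rrec = _unique_flank(right, index, min_flank, min_identity) if right else None
            if (lrec and rrec and lrec.target_name == rrec.target_name
                    and lrec.strand == rrec.strand == "+"):
                donor_seq = donor[lrec.target_name]
                # pin flank edges exactly with an infix alignment
                win_l = donor_seq[max(0, lrec.target_start - 500):lrec.target_end + 500]
                _, le, _ = locate_infix(left, win_l)
                donor_left = max(0, lrec.target_start - 500) + le
                win_r = donor_seq[max(0, rrec.target_start - 500):rrec.target_end + 500]
                rs, _, _ = locate_infix(right, win_r)
                donor_right = max(0, rrec.target_start - 500) + rs
                infill = donor_seq[donor_left:donor_right]
                if (0 < len(infill) <= max_fill and "N" not in infill.upper()):
                    seq = seq[:gap_start] + infill.lower() + seq[gap_end:]
                    events.append(FillEvent(
                        chrom, gap_start, gap_end, "spanned",
                        lrec.target_name, donor_left, donor_right,
                        len(infill), lrec.query_span, rrec.query_span,
                        lrec.identity, rrec.identity))
                    new_items.append(TilingSegment(
                        contig=f"{lrec.target_name}_fill_{donor_left}",
                        contig_start=0, contig_end=len(infill), orientation="+",
                        donor_chrom=lrec.target_name, donor_start=donor_left,
                        donor_end=donor_right, identity=1.0))
                    pos += len(infill)
                    filled = True
            if not filled:
                new_items.append(item)
                pos += item.size
        out[chrom] = seq
        new_plan[chrom] = _merge_segments(new_items)
    log.info("spanned fill closed %d gaps (%d bp)", len(events),
             sum(e.bases_inserted for e in events))
    return out, TilingPlan(new_plan), events


def _merge_segments(items: list) -> list:
    """Drop zero-size artifacts; keep alternation valid."""
    return [it for it in items
            if not (isinstance(it, TilingGap) and it.size <= 0)]


def donor_contigs(donor: Assembly) -> list[tuple[str, int, int]]:
    """N-delimited contigs of the donor, as (chrom, start, end)."""
    out = []
    for name in donor.names():
        seq = donor[name]
        prev = 0
        for m in re.finditer(r"[Nn]+", seq):
            if m.start() > prev:
                out.append((name, prev, m.start()))
            prev = m.end()
        if len(seq) > prev:
            out.append((name, prev, len(seq)))
    return out


def insert_fitting_contigs(assembly: Assembly, donor: Assembly,
                           plan: TilingPlan,
                           length_tolerance: float = 1.1,
                           length_slack: int = 200,
                           ) -> tuple[Assembly, TilingPlan, list[FillEvent]]:
    """Insert donor contigs that fit inside remaining gaps, 100 N each side.

    A donor contig (clipped to the gap's projected donor interval) fits when
    the clipped fragment is at least ``MIN_INSERT`` bp and the total
    inserted length is <= ``length_tolerance`` * gap estimate +
    ``length_slack``.  Mutually compatible fragments go in donor-coordinate
    order; otherwise the largest wins.
    """
    contigs = donor_contigs(donor)
    out = assembly.copy()
    new_plan: dict[str, list] = {}
    events: list[FillEvent] = []
    for chrom in plan.chromosomes():
        seq = out[chrom]
        new_items: list = []
        pos = 0
        for item in plan.plan[chrom]:
            if isinstance(item, TilingSegment):
                new_items.append(item)
                pos += item.length
                continue
            gap_start, gap_end = pos, pos + item.size
            budget = length_tolerance * item.size + length_slack
            frags = []
            if item.donor_chrom is not None and item.donor_end > item.donor_start:
                for cname, cs, ce in contigs:
                    if cname != item.donor_chrom:
                        continue
                    s, e = max(cs, item.donor_start), min(ce, item.donor_end)
                    if e - s >= MIN_INSERT:
                        frags.append((s, e))
            frags.sort()
            merged = [f for f in frags]
            total = sum(e - s for s, e in merged)
            if total > budget:
                merged = []
                for s, e in sorted(frags, key=lambda f: f[0] - f[1]):
                    if sum(q - p for p, q in merged) + (e - s) <= budget:
                        merged.append((s, e))
                merged.sort()
            if not merged:
                new_items.append(item)
                pos += item.size
                continue
            pieces = ["N" * FLANK_GAP]
            sub_items: list = [TilingGap(size=FLANK_GAP, donor_chrom=item.donor_chrom,
                                         donor_start=item.donor_start,
                                         donor_end=merged[0][0])]
            for i, (s, e) in enumerate(merged):
                frag = donor[item.donor_chrom][s:e].lower()
                pieces.append(frag)
                sub_items.append(TilingSegment(
                    contig=f"{item.donor_chrom}_fit_{s}", contig_start=0,
                    contig_end=len(frag), orientation="+",
                    donor_chrom=item.donor_chrom, donor_start=s, donor_end=e,
                    identity=1.0))
                nxt = merged[i + 1][0] if i + 1 < len(merged) else item.donor_end
                pieces.append("N" * FLANK_GAP)
                sub_items.append(TilingGap(size=FLANK_GAP,
                                           donor_chrom=item.donor_chrom,
                                           donor_start=e, donor_end=nxt))
                events.append(FillEvent(chrom, gap_start, gap_end, "fitted",
                                        item.donor_chrom, s, e, len(frag)))
            infill = "".join(pieces)
            seq = seq[:gap_start] + infill + seq[gap_end:]
            new_items.extend(sub_items)
            pos += len(infill)
        out[chrom] = seq
        new_plan[chrom] = new_items
    log.info("fitted %d donor contigs into gaps (%d bp)", len(events),
             sum(e.bases_inserted for e in events))
    return out, TilingPlan(new_plan), events


def donor_content_report(assembly: Assembly) -> dict:
    """Per-sequence and total uppercase/lowercase/N accounting."""
    per = {}
    tot = {"upper": 0, "lower": 0, "n": 0}
    for name in assembly.names():
        seq = assembly[name]
        n = sum(1 for c in seq if c in "Nn")
        lower = sum(1 for c in seq if c.islower() and c != "n")
        upper = len(seq) - n - lower
        frac = lower / (lower + upper) if lower + upper else 0.0
        per[name] = {"upper": upper, "lower": lower, "n": n,
                     "lower_fraction": frac}
        tot["upper"] += upper
        tot["lower"] += lower
        tot["n"] += n
    denom = tot["upper"] + tot["lower"]
    tot["lower_fraction"] = tot["lower"] / denom if denom else 0.0
    return {"per_sequence": per, "total": tot}


def total_gap_length(assembly: Assembly) -> int:
    return sum(g.length for g in assembly.all_gaps())
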