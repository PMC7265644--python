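"""Population major-allele harmonization.

Sites where a population's major allele (frequency > 0.5, reported in at
least ``min_count`` individuals) differs from the donor reference are
lifted onto the assembly through 2-kb anchored windows (span >= 1980 bp,
identity >= 99%, anchors unique in both sequences).  At each mapped site
the assembly base is classified and — only when the sample's own genotype
contains the major allele — replaced with it, preserving fidelity to the
underlying individual.  The final accounting is binned by major-allele
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import KmerIndex, anchor_align, lift_offset
from .model import Assembly, GenotypedVariant, revcomp

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_BIN_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class PopulationSite:
    donor_chrom: str
    donor_pos: int
    ref_allele: str       # donor reference base
    major_allele: str
    allele_frequency: float
    count: int
    # after mapping
    asm_chrom: str | None = None
    asm_pos: int | None = None
    asm_allele: str | None = None
    strand: str = "+"
    classification: str | None = None
    replaced: bool = False


def select_sites(table: pd.DataFrame, min_count: int = 200,
                 min_af: float = 0.5) -> list[PopulationSite]:
    """Keep single-base sites with count >= min_count and AF strictly > min_af.

    The alternate allele of a qualifying row is the population major
    allele; rows where it equals the donor reference are irrelevant and
    dropped.
    """
    out = []
    for row in table.itertuples(index=False):
        if row.count < min_count or not (row.af > min_af):
            continue
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue
        if row.ref == row.alt:
            continue
        out.append(PopulationSite(row.chrom, int(row.pos), row.ref.upper(),
                                  row.alt.upper(), float(row.af), int(row.count)))
    return out


def map_sites(sites: list[PopulationSite], donor: Assembly,
              assembly: Assembly | KmerIndex, window: int = 2_000,
              min_span: int = 1_980, min_identity: float = 0.99,
              ) -> tuple[list[PopulationSite], int]:
    """Lift each site through its centered window; return (mapped, n_unmapped).

    The window is anchor-aligned to the assembly with genome-wide-unique
    k-mers; chains below the span or identity floor are dropped, the best
    survivor (identity, then span, then lowest target coordinate) lifts
    the site base-exactly through the chain's edit path.  Sites whose
    window is clipped by a sequence end, that land in a gap column of the
    lift, or that have no surviving chain count as unmapped.
    """
    index = assembly if isinstance(assembly, KmerIndex) else KmerIndex(assembly)
    half = window // 2
    mapped: list[PopulationSite] = []
    unmapped = 0
    for site in sites:
        seq = donor[site.donor_chrom]
        lo, hi = site.donor_pos - half, site.donor_pos + half
        if lo < 0 or hi > len(seq):
            unmapped += 1
            continue
        win = seq[lo:hi]
        recs = [r for r in anchor_align(win, index, refine=True)
                if r.query_span >= min_span and r.identity >= min_identity]
        if not recs:
            unmapped += 1
            continue
        best = max(recs, key=lambda r: (r.identity, r.query_span,
                                        -r.target_start))
        offset = half - best.query_start
        tseq = index.target[best.target_name]
        if best.strand == "+":
            qseq = win[best.query_start:best.query_end]
            toff = lift_offset(qseq, tseq[best.target_start:best.target_end],
                               offset)
            if toff is None:
                unmapped += 1
                continue
            site.asm_pos = best.target_start + toff
            site.strand = "+"
        else:
            qseq = revcomp(win)[len(win) - best.query_end:
                                len(win) - best.query_start]
            off_rc = (len(win) - 1 - half) - (len(win) - best.query_end)
            toff = lift_offset(qseq, tseq[best.target_start:best.target_end],
                               off_rc)
            if toff is None:
                unmapped += 1
                continue
            site.asm_pos = best.target_start + toff
            site.strand = "-"
        site.asm_chrom = best.target_name
        site.asm_allele = tseq[site.asm_pos].upper()
        if site.strand == "-":
            site.asm_allele = COMPLEMENT.get(site.asm_allele, site.asm_allele)
        mapped.append(site)
    return mapped, unmapped


def classify_and_replace(sites: list[PopulationSite], assembly: Assembly,
                         genotypes: list[GenotypedVariant],
                         ) -> tuple[Assembly, pd.DataFrame]:
    """Classify every mapped site; install the major allele where the
    genotype permits.

    Buckets: *matched* (assembly already carries the major allele),
    *replaced* (assembly carried the donor allele at a heterozygous site
    whose genotype includes the major allele; base edited), *reference*
    (assembly carries the donor allele with no major allele in the
    genotype — left untouched), *third* (none of the above).  Edits only
    ever install the site's major allele.
    """
    gt_by_pos = {(g.chrom, g.pos): g for g in genotypes}
    out = assembly.copy()
    rows = []
    for site in sorted(sites, key=lambda s: (s.asm_chrom, s.asm_pos)):
        if site.asm_chrom is None:
            continue
        allele = out[site.asm_chrom][site.asm_pos]
        observed = allele.upper() if site.strand == "+" else COMPLEMENT[allele.upper()]
        g = gt_by_pos.get((site.donor_chrom, site.donor_pos))
        carried = g.carried_alleles() if g else {site.ref_allele}
        if observed == site.major_allele:
            site.classification = "matched"
        elif observed == site.ref_allele and site.major_allele in carried:
            base = site.major_allele if site.strand == "+" else COMPLEMENT[site.major_allele]
            base = base.lower() if allele.islower() else base
            seq = out[site.asm_chrom]
            out[site.asm_chrom] = (seq[:site.asm_pos] + base +
                                   seq[site.asm_pos + 1:])
            site.classification = "replaced"
            site.replaced = True
        elif observed == site.ref_allele:
            site.classification = "reference"
        else:
            site.classification = "third"
        site.asm_allele = observed
        rows.append((site.donor_chrom, site.donor_pos, site.ref_allele,
                     site.major_allele, site.allele_frequency,
                     site.asm_chrom, site.asm_pos, observed,
                     site.classification))
    acct = pd.DataFrame(rows, columns=[
        "donor_chrom", "donor_pos", "ref", "major", "af",
        "asm_chrom", "asm_pos", "asm_allele", "classification"])
    log.info("harmonization: %s", acct["classification"].value_counts().to_dict()
             if len(acct) else {})
    return out, acct


def af_binned_report(accounting: pd.DataFrame,
                     bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
                     ) -> pd.DataFrame:
    """Sites and matched proportion per major-allele-frequency bin.

    *Matched* counts sites that carry the major allele after harmonization
    (classes ``matched`` and ``replaced``).  Bins are half-open on the
    left, ``(edge_i, edge_{i+1}]``, following the convention that 0.5
    itself is excluded by site selection.
    """
    edges = list(bin_edges)
    labels = [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    cut = pd.cut(accounting["af"], bins=edges, labels=labels, right=True)
    rows = []
    for label in labels:
        sub = accounting[cut == label]
        n = len(sub)
        matched = int(sub["classification"].isin(["matched", "replaced"]).sum())
        rows.append((label, n, matched, matched / n if n else np.nan))
    total = len(accounting)
    matched = int(accounting["classification"].isin(["matched", "replaced"]).sum())
    rows.append(("total", total, matched, matched / total if total else np.nan))
    return pd.DataFrame(rows, columns=["af_bin", "sites", "matched", "proportion"])


def harmonize(table: pd.DataFrame, donor: Assembly, assembly: Assembly,
              genotypes: list[GenotypedVariant], window: int = 2_000,
              min_span: int = 1_980, min_identity: float = 0.99,
              min_count: int = 200, min_af: float = 0.5,
              ) -> tuple[Assembly, pd.DataFrame, pd.DataFrame, dict]:
    """Full harmonization stage; returns (assembly', accounting, bins, stats)."""
    sites = select_sites(table, min_count, min_af)
    mapped, unmapped = map_sites(sites, donor, assembly, window, min_span,
                                 min_identity)
    out, acct = classify_and_replace(mapped, assembly, genotypes)
    bins = af_binned_report(acct)
    stats = {"selected": len(sites), "mapped": len(mapped),
             "unmapped": unmapped,
             "replaced": int(acct["classification"].eq("replaced").sum())
             if len(acct) else 0}
    return out, acct, bins, stats
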