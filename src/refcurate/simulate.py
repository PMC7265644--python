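"""Synthetic diploid genomes with known truth, for end-to-end testing.

The generator emulates the inputs of a reference-guided curation project:
a finished donor reference, a diploid sample carrying SNVs (tagged with
population allele frequencies), small indels, structural variants >= 50 bp
and reciprocal subtelomeric translocations; a fragmented contig set with
chimeric joins and withheld intervals (future assembly gaps); read-coverage
tracks with dropouts at chimeric junctions; a population allele-frequency
site table; and a toy multi-isoform annotation with per-transcript truth
consequence labels.

Everything is drawn from one ``numpy`` generator seeded from the config, so
identical (seed, config) pairs give byte-identical outputs.

What this does NOT emulate: read-level errors, mapping biases, repeat
families beyond planted exact repeats, or assembly artifacts other than
fragmentation/chimerism and (optionally) planted consensus errors.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GffFeature
from .model import Assembly, CoverageTrack, GenotypedVariant, revcomp

BASES = np.array(list("ACGT"))

STOP_CODONS = ("TAA", "TAG", "TGA")

# protein-disruption categories, most consequential first
CONSEQUENCE_PRECEDENCE = [
    "unmapped", "truncated", "frameshift", "stop_gained", "stop_lost",
    "start_lost", "inframe_insertion", "inframe_deletion", "missense",
    "identical",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults are the study conditions.

    Rates are per base, sizes in bp.  ``seed`` drives every random choice.
    """
    seed: int = 1
    chromosome_lengths: tuple[int, ...] = (500_000, 500_000)
    chrom_prefix: str = "chr"
    # donor reference texture
    repeat_count: int = 2            # planted exact repeat pairs (tie-break fodder)
    repeat_length: int = 3_000
    donor_gap_count: int = 2         # N placeholders in the donor itself
    donor_gap_length: int = 800
    # small variants
    snv_rate: float = 1e-3
    indel_rate: float = 1e-4
    max_indel: int = 10
    population_site_fraction: float = 0.6
    af_high_fraction: float = 0.7    # AF-spectrum mass above 0.5
    low_count_sites: int = 10        # distractor rows reported in < 200 people
    multi_base_sites: int = 5        # distractor rows that are not single-base
    max_sample_count: int = 1662
    min_sample_count: int = 200
    # structural variants
    sv_count: int = 40
    sv_min_size: int = 50
    sv_max_size: int = 400
    sv_insertion_fraction: float = 0.5
    sv_hom_fraction: float = 0.456   # hom:het mix of the truth SV set
    # translocations (reciprocal terminal-segment exchanges)
    translocation_count: int = 1
    subtelomere_fraction: float = 0.01
    # fragmentation
    contig_n50: int = 60_000
    min_contig: int = 9_000
    chimera_count: int = 4
    withheld_intervals: int = 3
    withheld_min: int = 4_000
    withheld_max: int = 10_000
    withheld_over_donor_gap: int = 1  # withheld intervals straddling a donor N run
    inversion_fraction: float = 0.3
    # coverage model
    coverage_mean: int = 30
    coverage_jitter: int = 3
    junction_depth: int = 2
    junction_window: int = 4_000
    coverage_bin: int = 1_000
    # consensus errors planted into the sample assembly
    error_count: int = 200
    error_near_variant_fraction: float = 0.1   # planted within 30 bp of a true variant
    error_in_excluded_fraction: float = 0.1    # planted inside excluded regions
    # toy annotation
    gene_count: int = 20
    max_isoforms: int = 3
    paralog_deletions: int = 1   # genes deleted in the sample but with a planted paralog
    truncated_genes: int = 1     # genes losing >50% of their mRNA to a deletion

    def validate(self) -> None:
        for name in ("snv_rate", "indel_rate", "population_site_fraction",
                     "af_high_fraction", "sv_insertion_fraction",
                     "sv_hom_fraction", "subtelomere_fraction",
                     "inversion_fraction", "error_near_variant_fraction",
                     "error_in_excluded_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("chromosome_lengths", "contig_n50", "sv_min_size",
                     "coverage_bin"):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x <= 0 for x in vals):
                raise ValueError(f"{name} must be positive")
        if self.sv_min_size < 50:
            raise ValueError("structural variants are defined as >= 50 bp")


# ---------------------------------------------------------------------------
# coordinate bookkeeping
# ---------------------------------------------------------------------------

class ShiftMap:
    """Maps reference coordinates through a set of applied variants.

    ``events`` are ``(ref_start, ref_end, delta)`` spans replaced on one
    haplotype; positions strictly inside a replaced span (past its anchor
    base) have no image and lift to ``None``.
    """

    def __init__(self, events: list[tuple[int, int, int]]):
        self.events = sorted(events)
        self._starts = [s for s, _, _ in self.events]
        self._cum = []
        c = 0
        for _, _, d in self.events:
            c += d
            self._cum.append(c)

    def lift(self, pos: int) -> int | None:
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            return pos
        s, e, _ = self.events[i]
        if s < pos < e:
            return None
        shift = self._cum[i] if pos >= e else (self._cum[i - 1] if i > 0 else 0)
        if pos == s:  # anchor base: unshifted by its own event
            shift = self._cum[i - 1] if i > 0 else 0
        return pos + shift

    def lift_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Clip-lift: snap endpoints inside replaced spans to the span edge."""
        s = self.lift(start)
        i = bisect_right(self._starts, start) - 1
        if s is None:
            ev = self.events[i]
            s = self.lift(ev[1]) if ev[1] < end else None
        e = self.lift(end)
        if e is None:
            j = bisect_right(self._starts, end) - 1
            ev = self.events[j]
            e = self.lift(ev[0]) + 1 if ev[0] >= start else None
        if s is None or e is None or e <= s:
            return None
        return s, e


def apply_variants(seq: str, variants: list[GenotypedVariant]) -> tuple[str, ShiftMap]:
    """Apply non-overlapping, sorted variants to one sequence."""
    parts = []
    events = []
    prev = 0
    for v in variants:
        if v.pos < prev:
            raise ValueError(f"overlapping/unsorted variant at {v.chrom}:{v.pos}")
        alt = v.alts[0]
        parts.append(seq[prev:v.pos])
        parts.append(alt)
        prev = v.pos + len(v.ref)
        if len(alt) != len(v.ref) or alt != seq[v.pos:prev]:
            events.append((v.pos, prev, len(alt) - len(v.ref)))
    parts.append(seq[prev:])
    return "".join(parts), ShiftMap(events)


@dataclass
class Translocation:
    """Reciprocal exchange of terminal segments (reference coordinates)."""
    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int


@dataclass
class TiledPiece:
    """One source slice of a contig, in consensus-haplotype coordinates."""
    chrom: str
    start: int
    end: int
    orientation: str  # orientation of the slice inside the contig


@dataclass
class ChimeraJunction:
    contig: str
    offset: int          # junction position on the contig
    left_chrom: str
    right_chrom: str


@dataclass
class TruthSet:
    """Everything the generator knows, for parameter-recovery tests."""
    config: SimulationConfig
    reference: Assembly
    haplotypes: tuple[Assembly, Assembly]
    consensus: Assembly                     # haplotype 1 (+ planted errors)
    variants: list[GenotypedVariant]        # small variants, reference coords
    svs: list[GenotypedVariant]             # >=50 bp, reference coords
    translocations: list[Translocation]
    shift_maps: dict[tuple[int, str], ShiftMap]
    population_sites: pd.DataFrame = None
    planted_errors: list[GenotypedVariant] = field(default_factory=list)
    tiling: dict[str, list[TiledPiece]] = field(default_factory=dict)
    chimeras: list[ChimeraJunction] = field(default_factory=list)
    withheld_ref: list[tuple[str, int, int]] = field(default_factory=list)
    withheld: list[tuple[str, int, int]] = field(default_factory=list)
    annotation: list[GffFeature] = field(default_factory=list)
    projected_annotation: list[GffFeature] = field(default_factory=list)
    consequences: dict[str, str] = field(default_factory=dict)
    benchmark_regions: list[tuple[str, int, int]] = field(default_factory=list)
    excluded_regions: list[tuple[str, int, int]] = field(default_factory=list)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)
    donor_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    deleted_genes: list[str] = field(default_factory=list)
    paralog_of: dict[str, str] = field(default_factory=dict)

    def hap_variants(self, hap: int) -> dict[str, list[GenotypedVariant]]:
        """Variants (incl. SVs) carried by haplotype ``hap`` (0 or 1), per chrom."""
        out: dict[str, list[GenotypedVariant]] = {}
        for v in sorted(self.variants + self.svs, key=lambda v: (v.chrom, v.pos)):
            if v.genotype[hap] != 0:
                out.setdefault(v.chrom, []).append(v)
        return out

    def lift_to_consensus(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map a reference coordinate onto the consensus haplotype."""
        p = self.shift_maps[(0, chrom)].lift(pos)
        if p is None:
            return None
        for tr in self.translocations:
            ba = self.shift_maps[(0, tr.chrom_a)].lift(tr.breakpoint_a)
            bb = self.shift_maps[(0, tr.chrom_b)].lift(tr.breakpoint_b)
            if chrom == tr.chrom_a and p >= ba:
                return tr.chrom_b, bb + (p - ba)
            if chrom == tr.chrom_b and p >= bb:
                return tr.chrom_a, ba + (p - bb)
        return chrom, p


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[Assembly, list, list]:
    """Pseudo-random donor chromosomes with planted repeats and N gaps.

    Returns ``(assembly, repeat_intervals, donor_gap_intervals)``; repeats
    are exact duplicated segments (to exercise uniqueness tie-breaking) and
    donor gaps are N placeholders inside the donor itself.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    seqs = {}
    names = [f"{config.chrom_prefix}{i + 1}" for i in range(len(config.chromosome_lengths))]
    for name, length in zip(names, config.chromosome_lengths):
        seqs[name] = _random_seq(rng, length)

    repeats: list[tuple[str, int, int]] = []
    for _ in range(config.repeat_count):
        name = names[rng.integers(len(names))]
        L = config.repeat_length
        n = len(seqs[name])
        src = int(rng.integers(n // 8, n // 2 - L))
        dst = int(rng.integers(n // 2, 7 * n // 8 - L))
        block = seqs[name][src:src + L]
        seqs[name] = seqs[name][:dst] + block + seqs[name][dst + L:]
        repeats.append((name, src, src + L))
        repeats.append((name, dst, dst + L))

    donor_gaps: list[tuple[str, int, int]] = []
    for i in range(config.donor_gap_count):
        name = names[i % len(names)]
        L = config.donor_gap_length
        n = len(seqs[name])
        lo, hi = int(n * 0.15), int(n * 0.85)
        pos = int(rng.integers(lo, hi))
        if any(c == name and pos < e + 20_000 and s - 20_000 < pos + L
               for c, s, e in donor_gaps + repeats):
            pos = (lo + hi) // 2 + i * 25_000
        seqs[name] = seqs[name][:pos] + "N" * L + seqs[name][pos + L:]
        donor_gaps.append((name, pos, pos + L))

    return Assembly(seqs, validate=False), repeats, donor_gaps


# ---------------------------------------------------------------------------
# annotation layout (written into the reference before variants are drawn)
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]          # codon-aligned internal boundaries
    isoforms: dict[str, list[int]]        # transcript id -> exon indexes used


def _codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA, total (n_codons+2) codons."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(BASES[rng.integers(0, 4, size=3)])
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def simulate_annotation(reference: Assembly, config: SimulationConfig,
                        rng: np.random.Generator,
                        translocations: list[Translocation],
                        avoid: list[tuple[str, int, int]],
                        ) -> tuple[Assembly, list[GffFeature], list[_GenePlan]]:
    """Plant toy multi-isoform genes and return the rewritten reference.

    Gene CDS bases are written into the reference so every source CDS
    translates cleanly (ATG start, single terminal stop, no internal stop).
    Exon boundaries are codon-aligned, so skipping an internal exon yields
    another valid isoform.  At least one gene is placed inside each
    translocated terminal segment (when it fits) so annotation transfer
    sees the exchange.
    """
    ref = reference.copy()
    occupied = [(c, s - 200, e + 200) for c, s, e in avoid]
    plans: list[_GenePlan] = []

    def overlaps(chrom, s, e):
        return any(c == chrom and s < oe and os_ < e for c, os_, oe in occupied)

    def place_gene(idx: int, chrom: str, lo: int, hi: int) -> _GenePlan | None:
        n_exons = int(rng.integers(1, 4))
        exon_codons = [int(rng.integers(30, 90)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(80, 300)) for _ in range(n_exons - 1)]
        total = sum(c * 3 for c in exon_codons) + sum(intron_lens) + 6
        if hi - lo < total + 20:
            return None
        for _ in range(40):
            start = int(rng.integers(lo, hi - total))
            if not overlaps(chrom, start, start + total):
                break
        else:
            return None
        # build exon intervals; start codon in exon 0, stop in last exon
        exons = []
        pos = start
        cds = _codon_seq(rng, sum(exon_codons) - 2)  # -2: ATG/TAA live in the codon budget
        cpos = 0
        gseq = list(ref[chrom])
        for i, nc in enumerate(exon_codons):
            elen = nc * 3
            exons.append((pos, pos + elen))
            chunk = cds[cpos:cpos + elen]
            gseq[pos:pos + elen] = list(chunk)
            cpos += elen
            pos += elen
            if i < n_exons - 1:
                pos += intron_lens[i]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            # write the reverse complement so the spliced minus-strand CDS reads 5'->3'
            rc = revcomp(cds)
            cpos = 0
            for s_, e_ in exons:
                gseq[s_:e_] = list(rc[cpos:cpos + (e_ - s_)])
                cpos += e_ - s_
        ref[chrom] = "".join(gseq)
        end = exons[-1][1]
        occupied.append((chrom, start - 200, end + 200))
        gid = f"gene{idx:03d}"
        isoforms = {f"{gid}.t1": list(range(n_exons))}
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        if n_iso > 1 and n_exons >= 3:
            isoforms[f"{gid}.t2"] = [0] + list(range(2, n_exons))  # skip exon 1
        if n_iso > 2 and n_exons >= 3:
            isoforms[f"{gid}.t3"] = [0, n_exons - 1]
        return _GenePlan(gid, chrom, strand, start, end, exons, isoforms)

    idx = 0
    # one gene inside each translocated terminal segment
    for tr in translocations:
        for chrom, bp in ((tr.chrom_a, tr.breakpoint_a), (tr.chrom_b, tr.breakpoint_b)):
            plan = place_gene(idx, chrom, bp + 50, ref.length(chrom) - 50)
            if plan:
                plans.append(plan)
                idx += 1
    while idx < config.gene_count:
        chrom = ref.names()[int(rng.integers(len(ref)))]
        lo, hi = 1_000, ref.length(chrom) - 6_000
        plan = place_gene(idx, chrom, lo, hi)
        if plan:
            plans.append(plan)
        idx += 1

    features = gene_plans_to_gff(plans, source="refcurate-sim")
    return ref, features, plans


def gene_plans_to_gff(plans: list[_GenePlan], source: str) -> list[GffFeature]:
    feats = []
    for g in plans:
        feats.append(GffFeature(g.chrom, source, "gene", g.start, g.end, ".",
                                g.strand, ".", {"ID": g.gene_id}))
        for tid, exon_idx in g.isoforms.items():
            exons = [g.exons[i] for i in exon_idx]
            feats.append(GffFeature(g.chrom, source, "mRNA", exons[0][0],
                                    exons[-1][1], ".", g.strand, ".",
                                    {"ID": tid, "Parent": g.gene_id}))
            for s, e in exons:
                feats.append(GffFeature(g.chrom, source, "exon", s, e, ".",
                                        g.strand, ".", {"Parent": tid}))
                feats.append(GffFeature(g.chrom, source, "CDS", s, e, ".",
                                        g.strand, "0", {"Parent": tid}))
    return feats


def plant_paralogs(reference: Assembly, plans: list[_GenePlan],
                   gene_ids: list[str], rng: np.random.Generator,
                   divergence: float = 0.015
                   ) -> tuple[Assembly, dict[str, tuple[str, int, int]]]:
    """Copy each gene's body elsewhere with ~``divergence`` substitutions.

    The copies are unannotated paralogs: when the original is later deleted
    from the sample, a near-identical family member remains findable.
    """
    ref = reference.copy()
    by_id = {g.gene_id: g for g in plans}
    copies: dict[str, tuple[str, int, int]] = {}
    gene_spans = [(g.chrom, g.start - 500, g.end + 500) for g in plans]
    for gid in gene_ids:
        g = by_id[gid]
        body = ref[g.chrom][g.start:g.end]
        mutated = list(body)
        n_mut = max(1, rng.poisson(len(body) * divergence))
        for p in rng.integers(0, len(body), size=n_mut):
            if mutated[p] != "N":
                mutated[p] = str(rng.choice([b for b in "ACGT"
                                             if b != mutated[p].upper()]))
        for _ in range(100):
            chrom = ref.names()[int(rng.integers(len(ref)))]
            pos = int(rng.integers(10_000, ref.length(chrom) - 10_000 - len(body)))
            if (not any(c == chrom and pos < e and s < pos + len(body)
                        for c, s, e in gene_spans)
                    and "N" not in ref[chrom][pos:pos + len(body)]):
                break
        seq = ref[chrom]
        ref[chrom] = seq[:pos] + "".join(mutated) + seq[pos + len(body):]
        copies[gid] = (chrom, pos, pos + len(body))
        gene_spans.append((chrom, pos - 500, pos + len(body) + 500))
    return ref, copies


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

def _draw_positions(rng, length, n, occupied, margin=6, lo=1000, span=1):
    """n positions on [lo, length-lo) avoiding occupied +- margin."""
    out = []
    tries = 0
    while len(out) < n and tries < 50 * n + 100:
        tries += 1
        p = int(rng.integers(lo, length - lo - span))
        if all(p + span + margin <= s or p >= e + margin for s, e in occupied):
            occupied.append((p, p + span))
            out.append(p)
    occupied.sort()
    return out


def simulate_sample(reference: Assembly, config: SimulationConfig,
                    rng: np.random.Generator,
                    gene_plans: list[_GenePlan] | None = None,
                    translocations: list[Translocation] | None = None,
                    repeats: list[tuple[str, int, int]] | None = None,
                    donor_gaps: list[tuple[str, int, int]] | None = None,
                    genes_to_delete: list[str] | None = None,
                    genes_to_truncate: list[str] | None = None,
                    protected: list[tuple[str, int, int]] | None = None,
                    ) -> TruthSet:
    """Draw the diploid sample: variants, genotypes, haplotypes, truth VCF."""
    gene_plans = gene_plans or []
    translocations = translocations or []
    repeats = repeats or []
    donor_gaps = donor_gaps or []

    variants: list[GenotypedVariant] = []
    svs: list[GenotypedVariant] = []

    # regions where sequence variants must not land
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in reference.names()}
    for c, s, e in donor_gaps:
        forbidden[c].append((s - 10, e + 10))
    for tr in translocations:
        forbidden[tr.chrom_a].append((tr.breakpoint_a - 100, tr.breakpoint_a + 100))
        forbidden[tr.chrom_b].append((tr.breakpoint_b - 100, tr.breakpoint_b + 100))

    gene_bodies = {g.gene_id: (g.chrom, g.start, g.end) for g in gene_plans}

    def genotype_from_af(f: float) -> tuple[int, int]:
        r = rng.random()
        if r < (1 - f) ** 2:
            return (0, 0)
        if r < (1 - f) ** 2 + 2 * f * (1 - f):
            return (0, 1) if rng.random() < 0.5 else (1, 0)
        return (1, 1)

    for chrom in reference.names():
        seq = reference[chrom]
        length = len(seq)
        occupied = sorted(forbidden[chrom])

        n_snv = rng.poisson(length * config.snv_rate)
        n_pop = int(round(n_snv * config.population_site_fraction))
        pop_positions = _draw_positions(rng, length, n_pop, occupied)
        priv_positions = _draw_positions(rng, length, n_snv - n_pop, occupied)
        n_indel = rng.poisson(length * config.indel_rate)
        indel_positions = _draw_positions(rng, length, n_indel, occupied,
                                          span=config.max_indel + 2)

        for p in pop_positions:
            ref_base = seq[p]
            if ref_base == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            if rng.random() < config.af_high_fraction:
                af = float(rng.uniform(0.505, 0.995))
            else:
                af = float(rng.uniform(0.05, 0.495))
            gt = genotype_from_af(af)
            count = int(rng.integers(config.min_sample_count, config.max_sample_count + 1))
            v = GenotypedVariant(chrom, p, ref_base, (alt,), gt,
                                 allele_frequency=round(af, 4), sample_count=count,
                                 info={"POP": True})
            variants.append(v)

        for p in priv_positions:
            ref_base = seq[p]
            if ref_base == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            gt = (1, 1) if rng.random() < 0.4 else ((0, 1) if rng.random() < 0.5 else (1, 0))
            variants.append(GenotypedVariant(chrom, p, ref_base, (alt,), gt))

        for p in indel_positions:
            L = int(rng.integers(1, config.max_indel + 1))
            anchor = seq[p]
            if anchor == "N" or "N" in seq[p:p + L + 1]:
                continue
            gt = (1, 1) if rng.random() < 0.4 else ((0, 1) if rng.random() < 0.5 else (1, 0))
            if rng.random() < 0.5:
                ins = _random_seq(rng, L)
                variants.append(GenotypedVariant(chrom, p, anchor, (anchor + ins,), gt))
            else:
                refa = seq[p:p + 1 + L]
                variants.append(GenotypedVariant(chrom, p, refa, (anchor,), gt))

    # --- structural variants (avoid gene bodies and repeats) -------------
    sv_forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in reference.names()}
    for c in reference.names():
        sv_forbidden[c] = [(v.pos - 50, v.end + 50) for v in variants if v.chrom == c]
        sv_forbidden[c] += [(s - 100, e + 100) for g, (cc, s, e) in
                            (((gp.gene_id), (gp.chrom, gp.start, gp.end)) for gp in gene_plans)
                            if cc == c]
        sv_forbidden[c] += [(s, e) for cc, s, e in repeats + donor_gaps if cc == c]
        sv_forbidden[c] += [(s - 100, e + 100) for cc, s, e in (protected or [])
                            if cc == c]
        for tr in translocations:
            if c == tr.chrom_a:
                sv_forbidden[c].append((tr.breakpoint_a - 500, reference.length(c)))
            if c == tr.chrom_b:
                sv_forbidden[c].append((tr.breakpoint_b - 500, reference.length(c)))

    names = reference.names()
    for i in range(config.sv_count):
        chrom = names[int(rng.integers(len(names)))]
        seq = reference[chrom]
        L = int(rng.integers(config.sv_min_size, config.sv_max_size + 1))
        occ = sorted(sv_forbidden[chrom])
        pos_list = _draw_positions(rng, len(seq), 1, occ, margin=1500, span=L + 2)
        sv_forbidden[chrom] = occ
        if not pos_list:
            continue
        p = pos_list[0]
        anchor = seq[p]
        if anchor == "N" or "N" in seq[p:p + L + 1]:
            continue
        hom = rng.random() < config.sv_hom_fraction
        gt = (1, 1) if hom else ((0, 1) if rng.random() < 0.5 else (1, 0))
        if rng.random() < config.sv_insertion_fraction:
            ins = _random_seq(rng, L)
            svs.append(GenotypedVariant(chrom, p, anchor, (anchor + ins,), gt,
                                        info={"SVTYPE": "INS", "SVLEN": L}))
        else:
            refa = seq[p:p + 1 + L]
            svs.append(GenotypedVariant(chrom, p, refa, (anchor,), gt,
                                        info={"SVTYPE": "DEL", "SVLEN": -L}))

    # --- planted gene deletions (paralog / truncation cases) -------------
    deleted_genes: list[str] = []
    paralog_of: dict[str, str] = {}
    by_id = {g.gene_id: g for g in gene_plans}
    del_picks = [by_id[g] for g in (genes_to_delete or [])]
    trunc_picks = [by_id[g] for g in (genes_to_truncate or [])]
    for g in del_picks:
        seq = reference[g.chrom]
        refa = seq[g.start - 101: g.end + 100]
        svs.append(GenotypedVariant(g.chrom, g.start - 101, refa, (refa[0],), (1, 1),
                                    info={"SVTYPE": "DEL", "SVLEN": -(len(refa) - 1),
                                          "GENE_DELETION": g.gene_id}))
        deleted_genes.append(g.gene_id)
    for g in trunc_picks:
        # cut where 40% of the exonic bases have accumulated, so every
        # isoform keeps well under the 50% mapping threshold
        total_ex = sum(e - s for s, e in g.exons)
        acc, cut = 0, g.start
        for s, e in g.exons:
            if acc + (e - s) >= 0.4 * total_ex:
                cut = s + int(0.4 * total_ex) - acc
                break
            acc += e - s
            cut = e
        refa = reference[g.chrom][cut: g.end + 60]
        svs.append(GenotypedVariant(g.chrom, cut, refa, (refa[0],), (1, 1),
                                    info={"SVTYPE": "DEL", "SVLEN": -(len(refa) - 1),
                                          "GENE_TRUNCATION": g.gene_id}))

    # drop small variants swallowed by planted deletions
    del_spans = [(v.chrom, v.pos, v.end) for v in svs
                 if "GENE_DELETION" in v.info or "GENE_TRUNCATION" in v.info]
    variants = [v for v in variants
                if not any(c == v.chrom and v.pos >= s - 30 and v.end <= e + 30
                           for c, s, e in del_spans)]
    svs = [v for v in svs
           if ("GENE_DELETION" in v.info or "GENE_TRUNCATION" in v.info)
           or not any(c == v.chrom and v.pos < e + 30 and v.end > s - 30
                      for c, s, e in del_spans)]

    variants.sort(key=lambda v: (v.chrom, v.pos))
    svs.sort(key=lambda v: (v.chrom, v.pos))

    # --- haplotypes -------------------------------------------------------
    haps = []
    shift_maps: dict[tuple[int, str], ShiftMap] = {}
    for h in (0, 1):
        seqs = {}
        per_chrom: dict[str, list[GenotypedVariant]] = {c: [] for c in reference.names()}
        for v in sorted(variants + svs, key=lambda v: (v.chrom, v.pos)):
            if v.genotype[h] != 0:
                per_chrom[v.chrom].append(v)
        for chrom in reference.names():
            seqs[chrom], shift_maps[(h, chrom)] = apply_variants(
                reference[chrom], per_chrom[chrom])
        # reciprocal terminal exchange at variant-shifted breakpoints
        for tr in translocations:
            ba = shift_maps[(h, tr.chrom_a)].lift(tr.breakpoint_a)
            bb = shift_maps[(h, tr.chrom_b)].lift(tr.breakpoint_b)
            a, b = seqs[tr.chrom_a], seqs[tr.chrom_b]
            seqs[tr.chrom_a], seqs[tr.chrom_b] = a[:ba] + b[bb:], b[:bb] + a[ba:]
        haps.append(Assembly(seqs, validate=False))

    return TruthSet(
        config=config, reference=reference,
        haplotypes=(haps[0], haps[1]), consensus=haps[0].copy(),
        variants=variants, svs=svs, translocations=translocations,
        shift_maps=shift_maps, repeats=repeats, donor_gaps=donor_gaps,
        deleted_genes=deleted_genes, paralog_of=paralog_of)


# ---------------------------------------------------------------------------
# population site table
# ---------------------------------------------------------------------------

def simulate_population_sites(truth: TruthSet, config: SimulationConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Population AF site table (TSV form), with filter-fodder rows.

    Rows: every population-tagged truth SNV (ref allele = donor base, alt
    allele with its AF and report count), plus hom-ref sites drawn fresh,
    plus low-count and multi-base distractors.
    """
    rows = []
    for v in truth.variants:
        if v.info.get("POP"):
            rows.append((v.chrom, v.pos, v.ref, v.alts[0],
                         v.allele_frequency, v.sample_count))
    ref = truth.reference
    occupied = {c: sorted([(v.pos, v.end) for v in truth.variants + truth.svs
                           if v.chrom == c] +
                          [(s, e) for cc, s, e in truth.donor_gaps if cc == c])
                for c in ref.names()}
    # distractors: low report counts and multi-base substitutions
    chrom = ref.names()[0]
    occ = occupied[chrom]
    for p in _draw_positions(rng, ref.length(chrom), config.low_count_sites, occ):
        base = ref[chrom][p]
        if base == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        rows.append((chrom, p, base, alt, round(float(rng.uniform(0.505, 0.995)), 4),
                     int(rng.integers(20, config.min_sample_count))))
    for p in _draw_positions(rng, ref.length(chrom), config.multi_base_sites, occ):
        two = ref[chrom][p:p + 2]
        if "N" in two:
            continue
        alt = _random_seq(rng, 2)
        rows.append((chrom, p, two, alt, round(float(rng.uniform(0.505, 0.995)), 4),
                     int(rng.integers(config.min_sample_count, config.max_sample_count))))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af", "count"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# fragmentation, coverage, planted errors
# ---------------------------------------------------------------------------

def fragment_assembly(consensus: Assembly, config: SimulationConfig,
                      rng: np.random.Generator,
                      withheld: list[tuple[str, int, int]] | None = None,
                      ) -> tuple[Assembly, dict[str, list[TiledPiece]],
                                 list[ChimeraJunction]]:
    """Cut the consensus haplotype into contigs with chimeras and withheld gaps.

    Withheld intervals (consensus coordinates) are dropped entirely — they
    become the assembly gaps the donor fill step must close.  ``chimera_count``
    junctions concatenate chunks from different chromosomes.  Each emitted
    piece is reverse-complemented with probability ``inversion_fraction``.
    """
    withheld = withheld or []
    chunks: list[tuple[str, int, int]] = []
    for chrom in consensus.names():
        length = consensus.length(chrom)
        cuts = sorted([s for c, s, e in withheld if c == chrom] +
                      [e for c, s, e in withheld if c == chrom])
        segments = []
        prev = 0
        drop = {(s, e) for c, s, e in withheld if c == chrom}
        bounds = [0] + cuts + [length]
        for a, b in zip(bounds, bounds[1:]):
            if (a, b) not in drop and b > a:
                segments.append((a, b))
        for a, b in segments:
            pos = a
            while pos < b:
                target = int(rng.integers(config.contig_n50 // 2,
                                          config.contig_n50 * 3 // 2))
                end = min(pos + target, b)
                if b - end < config.min_contig:
                    end = b
                chunks.append((chrom, pos, end))
                pos = end

    # choose cross-chromosome pairs for chimeric joins
    order = list(rng.permutation(len(chunks)))
    big = [i for i in order if chunks[i][2] - chunks[i][1] >= config.min_contig]
    pairs = []
    used = set()
    for i in big:
        if len(pairs) == config.chimera_count:
            break
        if i in used:
            continue
        for j in big:
            if j in used or j == i or chunks[j][0] == chunks[i][0]:
                continue
            pairs.append((i, j))
            used.update((i, j))
            break

    contigs: dict[str, str] = {}
    tiling: dict[str, list[TiledPiece]] = {}
    chimeras: list[ChimeraJunction] = []

    def oriented(chrom, s, e):
        seq = consensus[chrom][s:e]
        if rng.random() < config.inversion_fraction:
            return revcomp(seq), "-"
        return seq, "+"

    emit_order = list(rng.permutation(len(chunks)))
    n = 0
    done = set()
    for i in emit_order:
        if i in done:
            continue
        pair = next((p for p in pairs if i in p), None)
        n += 1
        name = f"contig{n:04d}"
        if pair is None:
            chrom, s, e = chunks[i]
            seq, ori = oriented(chrom, s, e)
            contigs[name] = seq
            tiling[name] = [TiledPiece(chrom, s, e, ori)]
            done.add(i)
        else:
            a, b = pair
            ca, sa, ea = chunks[a]
            cb, sb, eb = chunks[b]
            seq_a, ori_a = oriented(ca, sa, ea)
            seq_b, ori_b = oriented(cb, sb, eb)
            contigs[name] = seq_a + seq_b
            tiling[name] = [TiledPiece(ca, sa, ea, ori_a),
                            TiledPiece(cb, sb, eb, ori_b)]
            chimeras.append(ChimeraJunction(name, len(seq_a), ca, cb))
            done.update(pair)
    return Assembly(contigs, validate=False), tiling, chimeras


def choose_withheld_intervals(truth: TruthSet, config: SimulationConfig,
                              rng: np.random.Generator
                              ) -> tuple[list[tuple[str, int, int]],
                                         list[tuple[str, int, int]]]:
    """Pick withheld intervals on reference coords, then lift to consensus.

    Intervals avoid genes, SVs, repeats and translocated tails so their
    flanks stay alignable; ``withheld_over_donor_gap`` of them deliberately
    straddle a donor N run (those gaps cannot be spanned by contiguous
    donor sequence and must wait for the contig-fitting fill step).
    """
    ref = truth.reference
    avoid: dict[str, list[tuple[int, int]]] = {c: [] for c in ref.names()}
    for c, s, e in truth.repeats:
        avoid[c].append((s - 3000, e + 3000))
    for v in truth.svs:
        avoid[v.chrom].append((v.pos - 3000, v.end + 3000))
    for tr in truth.translocations:
        avoid[tr.chrom_a].append((tr.breakpoint_a - 6000, ref.length(tr.chrom_a)))
        avoid[tr.chrom_b].append((tr.breakpoint_b - 6000, ref.length(tr.chrom_b)))
    for g, s, e in truth.donor_gaps:
        avoid[g].append((s - 6000, e + 6000))
    for ft in truth.annotation:
        if ft.type == "gene":
            avoid[ft.seqid].append((ft.start - 1500, ft.end + 1500))

    out_ref: list[tuple[str, int, int]] = []
    n_over = min(config.withheld_over_donor_gap, len(truth.donor_gaps),
                 config.withheld_intervals)
    for c, s, e in truth.donor_gaps[:n_over]:
        pad_l = int(rng.integers(1200, 2500))
        pad_r = int(rng.integers(1200, 2500))
        out_ref.append((c, s - pad_l, e + pad_r))
    names = ref.names()
    tries = 0
    while len(out_ref) < config.withheld_intervals and tries < 200:
        tries += 1
        chrom = names[int(rng.integers(len(names)))]
        L = int(rng.integers(config.withheld_min, config.withheld_max + 1))
        p = int(rng.integers(20_000, ref.length(chrom) - 20_000 - L))
        window = (p - 6000, p + L + 6000)
        if any(s < window[1] and window[0] < e for s, e in avoid[chrom]):
            continue
        if any(c == chrom and s < window[1] and window[0] < e for c, s, e in out_ref):
            continue
        out_ref.append((chrom, p, p + L))

    out_cons = []
    for c, s, e in out_ref:
        lifted = truth.lift_to_consensus(c, s), truth.lift_to_consensus(c, e)
        if lifted[0] is None or lifted[1] is None:
            continue
        (c1, s1), (c2, e1) = lifted
        if c1 == c2 and e1 > s1:
            out_cons.append((c1, s1, e1))
    return out_ref, out_cons


def simulate_coverage(contigs: Assembly, chimeras: list[ChimeraJunction],
                      config: SimulationConfig, rng: np.random.Generator
                      ) -> CoverageTrack:
    """Uniform jittered depth, with a dropout/pile-up window at each junction."""
    junctions = {}
    for ch in chimeras:
        junctions.setdefault(ch.contig, []).append(ch.offset)
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    w = config.junction_window // 2
    for name in contigs.names():
        length = contigs.length(name)
        ivs = []
        pos = 0
        while pos < length:
            end = min(pos + config.coverage_bin, length)
            depth = int(config.coverage_mean +
                        rng.integers(-config.coverage_jitter,
                                     config.coverage_jitter + 1))
            ivs.append([pos, end, float(depth)])
            pos = end
        for j in junctions.get(name, []):
            lo, hi = max(0, j - w), min(length, j + w)
            new = []
            for s, e, d in ivs:
                if e <= lo or s >= hi:
                    new.append([s, e, d])
                    continue
                if s < lo:
                    new.append([s, lo, d])
                new.append([max(s, lo), min(e, hi), float(config.junction_depth)])
                if e > hi:
                    new.append([hi, e, d])
            merged = []
            for s, e, d in sorted(new):
                if merged and merged[-1][1] == s and merged[-1][2] == d:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, d])
            ivs = merged
        intervals[name] = [(s, e, d) for s, e, d in ivs]
    return CoverageTrack(intervals)


def plant_duplicate_contigs(contigs: Assembly, n: int,
                            rng: np.random.Generator,
                            length: int = 15_000,
                            mutation_rate: float = 0.01
                            ) -> tuple[Assembly, list[str]]:
    """Plant haplotype-duplicate contigs: mutated slices of larger contigs."""
    out = contigs.copy()
    big = [c for c in contigs.names() if contigs.length(c) >= 2 * length]
    planted = []
    for i in range(n):
        src = big[int(rng.integers(len(big)))]
        s = int(rng.integers(0, contigs.length(src) - length))
        seq = list(contigs[src][s:s + length])
        n_mut = rng.poisson(length * mutation_rate)
        for p in rng.integers(0, length, size=n_mut):
            if seq[p] != "N":
                seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p].upper()]))
        name = f"dup{i + 1:03d}"
        out[name] = "".join(seq)
        planted.append(name)
    return out, planted


def plant_errors(truth: TruthSet, config: SimulationConfig,
                 rng: np.random.Generator) -> None:
    """Plant consensus errors into ``truth.consensus`` (in place).

    Errors are chosen on donor coordinates inside the benchmark regions and
    recorded as the haploid calls a caller should report
    (``truth.planted_errors``).  A configured fraction lands within 30 bp
    of a true variant (proximity-filter fodder) and inside excluded regions
    (self-chain analogue fodder); the rest are the correctable errors.
    """
    if config.error_count == 0:
        return
    ref = truth.reference
    var_pos = {c: sorted(v.pos for v in truth.variants + truth.svs if v.chrom == c)
               for c in ref.names()}

    def near_variant(chrom, p, dist):
        arr = var_pos[chrom]
        i = bisect_right(arr, p)
        return ((i > 0 and p - arr[i - 1] <= dist) or
                (i < len(arr) and arr[i] - p <= dist))

    def in_regions(regions, chrom, p):
        return any(c == chrom and s <= p < e for c, s, e in regions)

    n_near = int(round(config.error_count * config.error_near_variant_fraction))
    n_excl = int(round(config.error_count * config.error_in_excluded_fraction))
    n_clean = config.error_count - n_near - n_excl

    placed = []
    tries = 0
    while (len(placed) < config.error_count and tries < 200 * config.error_count):
        tries += 1
        kind = ("near" if sum(1 for k, *_ in placed if k == "near") < n_near else
                "excl" if sum(1 for k, *_ in placed if k == "excl") < n_excl else
                "clean")
        chrom = ref.names()[int(rng.integers(len(ref)))]
        p = int(rng.integers(3000, ref.length(chrom) - 3000))
        if not in_regions(truth.benchmark_regions, chrom, p):
            continue
        if any(c == chrom and abs(q - p) < 40 for k, c, q in placed):
            continue
        if kind == "near":
            arr = var_pos[chrom]
            if not arr:
                continue
            i = min(bisect_right(arr, p), len(arr) - 1)
            p = arr[i] + int(rng.integers(5, 30))
            if not in_regions(truth.benchmark_regions, chrom, p):
                continue
            if in_regions(truth.excluded_regions, chrom, p):
                continue
        elif kind == "excl":
            cands = [(c, s, e) for c, s, e in truth.excluded_regions
                     if any(cc == c and s >= bs and e <= be for cc, bs, be
                            in truth.benchmark_regions) or True]
            c, s, e = cands[int(rng.integers(len(cands)))]
            chrom, p = c, int(rng.integers(s + 10, e - 10))
            if not in_regions(truth.benchmark_regions, chrom, p):
                continue
            if near_variant(chrom, p, 35):
                continue
        else:
            if near_variant(chrom, p, 35):
                continue
            if in_regions(truth.excluded_regions, chrom, p):
                continue
        lifted = truth.lift_to_consensus(chrom, p)
        if lifted is None:
            continue
        lc, lp = lifted
        base = truth.consensus[lc][lp]
        if base == "N" or base != ref[chrom][p]:
            continue
        placed.append((kind, chrom, p))
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        seq = truth.consensus[lc]
        truth.consensus[lc] = seq[:lp] + alt + seq[lp + 1:]
        truth.planted_errors.append(GenotypedVariant(
            chrom, p, ref[chrom][p], (alt,), (1,), info={"KIND": kind}))
    truth.planted_errors.sort(key=lambda v: (v.chrom, v.pos))


# ---------------------------------------------------------------------------
# projection of annotation + truth consequence labels
# ---------------------------------------------------------------------------

def _lift_exon(truth: TruthSet, chrom: str, start: int, end: int
               ) -> tuple[str, int, int] | None:
    sm = truth.shift_maps[(0, chrom)]
    iv = sm.lift_interval(start, end)
    if iv is None:
        return None
    s, e = iv
    res_s = truth.lift_to_consensus(chrom, start)
    res_e = truth.lift_to_consensus(chrom, end)
    if res_s and res_e and res_s[0] == res_e[0] and res_e[1] > res_s[1]:
        return res_s[0], res_s[1], res_e[1]
    # endpoint fell inside a deleted span: fall back to clip-lift, then map
    # through the exchange using the clipped start
    for tr in truth.translocations:
        ba = truth.shift_maps[(0, tr.chrom_a)].lift(tr.breakpoint_a)
        bb = truth.shift_maps[(0, tr.chrom_b)].lift(tr.breakpoint_b)
        if chrom == tr.chrom_a and s >= ba:
            return tr.chrom_b, bb + (s - ba), bb + (e - ba)
        if chrom == tr.chrom_b and s >= bb:
            return tr.chrom_a, ba + (s - bb), ba + (e - bb)
    return chrom, s, e


def project_annotation(truth: TruthSet) -> list[GffFeature]:
    """Lift the reference annotation onto the consensus haplotype.

    Genes wholly inside a sample deletion disappear; exons are clip-lifted
    through indels, so a partially deleted gene keeps its surviving exons.
    """
    out: list[GffFeature] = []
    by_parent: dict[str, list[GffFeature]] = {}
    genes = [ft for ft in truth.annotation if ft.type == "gene"]
    for ft in truth.annotation:
        if ft.type != "gene":
            by_parent.setdefault(ft.parent, []).append(ft)
    for gene in genes:
        lifted_children: list[GffFeature] = []
        for mrna in by_parent.get(gene.id, []):
            exon_feats = [f for f in by_parent.get(mrna.id, [])]
            lifted_exons = []
            for ft in exon_feats:
                hit = _lift_exon(truth, ft.seqid, ft.start, ft.end)
                if hit is None:
                    continue
                c, s, e = hit
                lifted_exons.append(GffFeature(c, ft.source, ft.type, s, e,
                                               ft.score, ft.strand, ft.phase,
                                               dict(ft.attributes)))
            if not any(f.type == "exon" for f in lifted_exons):
                continue
            exs = [f for f in lifted_exons if f.type == "exon"]
            lifted_children.append(GffFeature(
                exs[0].seqid, mrna.source, mrna.type,
                min(f.start for f in exs), max(f.end for f in exs),
                mrna.score, mrna.strand, mrna.phase, dict(mrna.attributes)))
            lifted_children.extend(lifted_exons)
        if not lifted_children:
            continue
        mrnas = [f for f in lifted_children if f.type in ("mRNA", "transcript")]
        out.append(GffFeature(mrnas[0].seqid, gene.source, "gene",
                              min(f.start for f in mrnas),
                              max(f.end for f in mrnas),
                              gene.score, gene.strand, gene.phase,
                              dict(gene.attributes)))
        out.extend(lifted_children)
    return out


def translate_full(cds: str) -> str:
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


def label_consequence(src_cds: str, tgt_cds: str | None,
                      status: str = "mapped") -> str:
    """Classify the protein-level effect of a source->target CDS change.

    Frameshift is judged by net CDS length difference mod 3 (compensating
    indel pairs therefore read as in-frame with a garbled stretch).  The
    most consequential applicable category wins, in
    :data:`CONSEQUENCE_PRECEDENCE` order.
    """
    if status == "unmapped" or tgt_cds is None:
        return "unmapped"
    if status == "partial":
        return "truncated"
    src_cds, tgt_cds = src_cds.upper(), tgt_cds.upper()
    if src_cds == tgt_cds:
        return "identical"
    flags = set()
    if (len(tgt_cds) - len(src_cds)) % 3 != 0:
        flags.add("frameshift")
    prot = translate_full(tgt_cds)
    src_prot = translate_full(src_cds)
    if tgt_cds[:3] != "ATG" and src_cds[:3] == "ATG":
        flags.add("start_lost")
    if "*" in prot[:-1]:
        flags.add("stop_gained")
    if src_prot.endswith("*") and not prot.endswith("*"):
        flags.add("stop_lost")
    if not flags:
        if len(tgt_cds) > len(src_cds):
            flags.add("inframe_insertion")
        elif len(tgt_cds) < len(src_cds):
            flags.add("inframe_deletion")
        elif prot != src_prot:
            flags.add("missense")
    if not flags:
        return "identical"
    for cat in CONSEQUENCE_PRECEDENCE:
        if cat in flags:
            return cat
    return "identical"


def truth_consequences(truth: TruthSet) -> dict[str, str]:
    """Per-transcript truth labels from the generator's own bookkeeping."""
    from .transcripts import extract_transcript_sequences
    src = extract_transcript_sequences(truth.reference, truth.annotation)
    tgt = extract_transcript_sequences(truth.consensus, truth.projected_annotation)
    labels = {}
    for tid, s in src.items():
        t = tgt.get(tid)
        if t is None or not t.mrna:
            labels[tid] = "unmapped"
        elif len(t.mrna) < 0.5 * len(s.mrna):
            labels[tid] = "truncated"
        else:
            labels[tid] = label_consequence(s.cds, t.cds, "mapped")
    return labels


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    truth: TruthSet
    contigs: Assembly
    coverage: CoverageTrack

    @property
    def reference(self) -> Assembly:
        return self.truth.reference

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config


def _plan_translocations(reference: Assembly, config: SimulationConfig,
                         rng: np.random.Generator) -> list[Translocation]:
    names = reference.names()
    out = []
    for i in range(config.translocation_count):
        if len(names) < 2:
            break
        a, b = names[(2 * i) % len(names)], names[(2 * i + 1) % len(names)]
        la, lb = reference.length(a), reference.length(b)
        sub_a = max(int(la * config.subtelomere_fraction), 3000)
        sub_b = max(int(lb * config.subtelomere_fraction), 3000)
        bp_a = la - int(rng.integers(2500, sub_a + 1))
        bp_b = lb - int(rng.integers(2500, sub_b + 1))
        out.append(Translocation(a, bp_a, b, bp_b))
    return out


def _benchmark_regions(truth: TruthSet) -> list[tuple[str, int, int]]:
    """Donor-coordinate confident regions: away from SVs, gaps, tails, ends."""
    ref = truth.reference
    masks: dict[str, list[tuple[int, int]]] = {c: [] for c in ref.names()}
    for v in truth.svs:
        masks[v.chrom].append((v.pos - 1000, v.end + 1000))
    for c, s, e in truth.donor_gaps:
        masks[c].append((s - 500, e + 500))
    for c, s, e in truth.withheld_ref:
        masks[c].append((s - 1000, e + 1000))
    for tr in truth.translocations:
        masks[tr.chrom_a].append((tr.breakpoint_a - 2000, ref.length(tr.chrom_a)))
        masks[tr.chrom_b].append((tr.breakpoint_b - 2000, ref.length(tr.chrom_b)))
    regions = []
    for chrom in ref.names():
        length = ref.length(chrom)
        mask = sorted([(max(0, s), min(length, e)) for s, e in masks[chrom]] +
                      [(0, 2000), (length - 2000, length)])
        merged = []
        for s, e in mask:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        prev = 0
        for s, e in merged:
            if s > prev:
                regions.append((chrom, prev, s))
            prev = max(prev, e)
        if prev < length:
            regions.append((chrom, prev, length))
    return regions


def simulate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator: reference, sample, contigs, tracks, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference, repeats, donor_gaps = simulate_reference(config, rng)
    translocations = _plan_translocations(reference, config, rng)
    avoid = repeats + donor_gaps
    reference, annotation, gene_plans = simulate_annotation(
        reference, config, rng, translocations, avoid)
    # choose genes for planted deletions / truncations, avoiding
    # translocated tails so each scenario stays cleanly attributable
    candidates = [g for g in gene_plans
                  if not any((tr.chrom_a == g.chrom and g.start >= tr.breakpoint_a - 200)
                             or (tr.chrom_b == g.chrom and g.start >= tr.breakpoint_b - 200)
                             for tr in translocations)]
    order = [candidates[i] for i in rng.permutation(len(candidates))]
    genes_to_delete = [g.gene_id for g in order[:config.paralog_deletions]]
    genes_to_truncate = [g.gene_id for g in
                         order[config.paralog_deletions:
                               config.paralog_deletions + config.truncated_genes]]
    reference, paralog_copies = plant_paralogs(reference, gene_plans,
                                               genes_to_delete, rng)
    truth = simulate_sample(reference, config, rng, gene_plans,
                            translocations, repeats, donor_gaps,
                            genes_to_delete, genes_to_truncate,
                            protected=list(paralog_copies.values()))
    truth.annotation = annotation
    truth.paralog_of = {gid: f"{c}:{s}-{e}"
                        for gid, (c, s, e) in paralog_copies.items()}
    truth.population_sites = simulate_population_sites(truth, config, rng)
    # hom-ref population draws exist only as site-table rows, not variants
    truth.variants = [v for v in truth.variants if set(v.genotype) != {0}]
    truth.withheld_ref, truth.withheld = choose_withheld_intervals(truth, config, rng)
    truth.benchmark_regions = _benchmark_regions(truth)
    truth.excluded_regions = [(c, max(0, s - 4500), e + 4500)
                              for c, s, e in truth.repeats]
    plant_errors(truth, config, rng)
    contigs, tiling, chimeras = fragment_assembly(truth.consensus, config, rng,
                                                  truth.withheld)
    truth.tiling = tiling
    truth.chimeras = chimeras
    coverage = simulate_coverage(contigs, chimeras, config, rng)
    truth.projected_annotation = project_annotation(truth)
    truth.consequences = truth_consequences(truth)
    return SyntheticDataset(truth=truth, contigs=contigs, coverage=coverage)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["chromosome_lengths"] = list(d["chromosome_lengths"])
    return d
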