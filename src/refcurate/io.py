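"""Readers and writers for the standard formats the pipeline speaks.

All writers emit deterministic column order and ``\\n`` line endings.
Internal coordinates are 0-based half-open; VCF, GFF3 and AGP are shifted
to 1-based inclusive at this boundary, PAF and BED stay 0-based half-open,
per each format's own convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .model import (AlignmentRecord, Assembly, CoverageTrack, GenotypedVariant,
                    TilingGap, TilingPlan, TilingSegment, validate_sequence)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Assembly:
    """Read a (case-significant) FASTA file into an :class:`Assembly`.

    Raises ``ValueError`` naming the offending record on characters outside
    {A,C,G,T,N}; an empty file yields an empty Assembly with a warning.
    """
    path = Path(path)
    text_head = path.read_text()[:1].strip()
    if text_head and text_head != ">":
        raise ValueError(f"{path}: malformed FASTA, first record does not start with '>'")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        try:
            validate_sequence(seq, rec.id)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        log.warning("FASTA file %s contains no records", path)
    return Assembly(sequences, validate=False)


def write_fasta(assembly: Assembly, path: str | Path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in assembly.names():
            fh.write(f">{name}\n")
            seq = assembly[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(f)}")
            strand = "+" if f[4] in "+" else "-"
            if f[4] not in ("+", "-", "−"):
                raise ValueError(f"{path}:{lineno}: bad strand {f[4]!r}")
            try:
                rec = AlignmentRecord(
                    query_name=f[0], query_length=int(f[1]),
                    query_start=int(f[2]), query_end=int(f[3]), strand=strand,
                    target_name=f[5], target_length=int(f[6]),
                    target_start=int(f[7]), target_end=int(f[8]),
                    matches=int(f[9]), block_length=int(f[10]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_paf(records: list[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            mapq = 60
            fh.write("\t".join(map(str, [
                r.query_name, r.query_length, r.query_start, r.query_end,
                r.strand, r.target_name, r.target_length, r.target_start,
                r.target_end, r.matches, r.block_length, mapq])) + "\n")


# ---------------------------------------------------------------------------
# VCF (via pysam)
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency per ALT">',
    '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of individuals the site was reported in">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def read_vcf(path: str | Path) -> list[GenotypedVariant]:
    """Read a VCF into :class:`GenotypedVariant` records (0-based positions).

    Sites-only VCFs get a default hom-alt genotype.  AF/NS/SVTYPE/SVLEN
    INFO fields are lifted into the dataclass; unknown sequence names are
    accepted (validation against an assembly happens downstream).
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue
            if samples:
                gt = rec.samples[samples[0]].get("GT")
                genotype = tuple(0 if g is None else g for g in gt) if gt else (1,)
            else:
                genotype = (1,) * 1
            info = dict(rec.info)
            af = info.pop("AF", None)
            if isinstance(af, tuple):
                af = af[0]
            ns = info.pop("NS", None)
            out.append(GenotypedVariant(
                chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alts=alts,
                genotype=genotype,
                allele_frequency=float(af) if af is not None else None,
                sample_count=int(ns) if ns is not None else None,
                info=info))
    return out


def write_vcf(variants: list[GenotypedVariant], path: str | Path,
              contig_lengths: dict[str, int] | None = None,
              sample: str = "SAMPLE") -> None:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    contigs: dict[str, int | None] = {}
    if contig_lengths:
        contigs.update(contig_lengths)
    for v in variants:
        contigs.setdefault(v.chrom, None)
    for name, length in contigs.items():
        if length is None:
            header.add_line(f"##contig=<ID={name}>")
        else:
            header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alts)):
            rec = vf.new_record(contig=v.chrom, start=v.pos,
                                alleles=(v.ref,) + v.alts)
            if v.allele_frequency is not None:
                rec.info["AF"] = float(v.allele_frequency)
            if v.sample_count is not None:
                rec.info["NS"] = int(v.sample_count)
            for key in ("SVTYPE", "SVLEN"):
                if key in v.info:
                    rec.info[key] = v.info[key]
            rec.samples[sample]["GT"] = tuple(v.genotype)
            vf.write(rec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: coordinate inversion {start} >= {end}")
            out.append((chrom, start, end))
    return out


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass
class GffFeature:
    """One GFF3 feature line; ``start`` is 0-based half-open internally."""
    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(f)}")
            start, end = int(f[3]) - 1, int(f[4])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: coordinate inversion")
            attrs = {}
            for kv in f[8].split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip()
            feats.append(GffFeature(f[0], f[1], f[2], start, end, f[5], f[6], f[7], attrs))
    return feats


def write_gff3(features: list[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features:
            attrs = ";".join(f"{k}={v}" for k, v in ft.attributes.items())
            fh.write("\t".join(map(str, [
                ft.seqid, ft.source, ft.type, ft.start + 1, ft.end,
                ft.score, ft.strand, ft.phase, attrs])) + "\n")


# ---------------------------------------------------------------------------
# AGP 2.1
# ---------------------------------------------------------------------------

def write_agp(plan: TilingPlan, path: str | Path) -> None:
    """Serialize a tiling plan as AGP 2.1 (W rows for contigs, N for gaps)."""
    plan.validate()
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for chrom in plan.chromosomes():
            pos = 0
            part = 0
            for item in plan.plan[chrom]:
                part += 1
                if isinstance(item, TilingSegment):
                    length = item.length
                    fh.write("\t".join(map(str, [
                        chrom, pos + 1, pos + length, part, "W",
                        item.contig, item.contig_start + 1, item.contig_end,
                        item.orientation])) + "\n")
                else:
                    length = item.size
                    fh.write("\t".join(map(str, [
                        chrom, pos + 1, pos + length, part, "N",
                        item.size, "scaffold", "yes", "align_genus"])) + "\n")
                pos += length


def read_agp(path: str | Path) -> TilingPlan:
    plan: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: AGP needs 9 columns")
            chrom = f[0]
            items = plan.setdefault(chrom, [])
            if f[4] == "W":
                items.append(TilingSegment(
                    contig=f[5], contig_start=int(f[6]) - 1, contig_end=int(f[7]),
                    orientation=f[8]))
            elif f[4] in ("N", "U"):
                items.append(TilingGap(size=int(f[5])))
            else:
                raise ValueError(f"{path}:{lineno}: unsupported component type {f[4]!r}")
    tp = TilingPlan(plan)
    tp.validate()
    return tp


# ---------------------------------------------------------------------------
# coverage tracks (BED-graph-like TSV) and site tables
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path) -> CoverageTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, s, e, d = line.split("\t")
            intervals.setdefault(name, []).append((int(s), int(e), float(d)))
    return CoverageTrack(intervals)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, ivs in track.intervals.items():
            for s, e, d in ivs:
                fh.write(f"{name}\t{s}\t{e}\t{d:g}\n")


SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "count"]


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Population allele-frequency site table (TSV; ``pos`` 1-based on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: site table missing columns {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[SITE_COLUMNS].to_csv(path, sep="\t", index=False)
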