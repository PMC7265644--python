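"""Core domain types shared by every pipeline stage.

Conventions
-----------
* All internal coordinates are 0-based half-open.  Conversion to the 1-based
  conventions of VCF / GFF3 / AGP happens only inside the format readers and
  writers in :mod:`refcurate.io`.
* Sequence case is significant: uppercase bases are native to the sample
  assembly, lowercase bases were copied in from the donor reference during
  gap filling, and ``N`` marks a gap.  Every operation must preserve case
  unless its whole point is to change it.
* Only ``{A,C,G,T,N}`` (either case) are accepted; degenerate IUPAC codes
  are rejected at ingest because base-level comparison logic downstream
  assumes an unambiguous alphabet.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, name: str = "<sequence>") -> None:
    """Raise ``ValueError`` on any character outside {A,C,G,T,N} (any case)."""
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"sequence {name!r} contains invalid characters: {bad}")


class Assembly:
    """A named collection of DNA sequences with per-base provenance.

    The case channel encodes provenance (uppercase native, lowercase
    donor-derived); ``metadata`` carries a free-form per-sequence dict
    (version tag, source, ...).
    """

    def __init__(self, sequences: dict[str, str] | None = None,
                 metadata: dict[str, dict] | None = None, validate: bool = True):
        self.sequences: dict[str, str] = dict(sequences or {})
        self.metadata: dict[str, dict] = dict(metadata or {})
        if validate:
            for name, seq in self.sequences.items():
                validate_sequence(seq, name)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __setitem__(self, name: str, seq: str) -> None:
        validate_sequence(seq, name)
        self.sequences[name] = seq

    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def copy(self) -> "Assembly":
        return Assembly(dict(self.sequences),
                        {k: dict(v) for k, v in self.metadata.items()},
                        validate=False)

    # -- gap bookkeeping ---------------------------------------------------

    def gaps(self, name: str, include_terminal: bool = False) -> list["Gap"]:
        """Runs of N in one sequence.

        Leading and trailing N runs are representable but by convention are
        not counted as gaps unless ``include_terminal`` is set.
        """
        seq = self.sequences[name]
        out = []
        for m in re.finditer(r"[Nn]+", seq):
            s, e = m.span()
            if not include_terminal and (s == 0 or e == len(seq)):
                continue
            out.append(Gap(name, s, e, estimated_size=e - s))
        return out

    def all_gaps(self, include_terminal: bool = False) -> list["Gap"]:
        out: list[Gap] = []
        for name in self.sequences:
            out.extend(self.gaps(name, include_terminal=include_terminal))
        return out


@dataclass(frozen=True)
class Gap:
    """A run of N within a sequence (0-based half-open span)."""
    sequence: str
    start: int
    end: int
    estimated_size: int = 0
    origin: str = "assembly"  # "assembly" | "flank-100N"

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError(f"gap span must be >= 1: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """A PAF-like interval match between a query and a target sequence.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; for ``strand == '-'`` increasing query coordinates correspond
    to decreasing target coordinates (PAF convention).
    """
    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    block_length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(f"bad query interval in {self}")
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise ValueError(f"bad target interval in {self}")
        if self.block_length <= 0 or not (0 <= self.matches <= self.block_length):
            raise ValueError(f"bad matches/block_length in {self}")

    @property
    def identity(self) -> float:
        return self.matches / self.block_length

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class GenotypedVariant:
    """A VCF-like site with alleles and a (haploid or diploid) genotype.

    ``pos`` is 0-based internally; the VCF reader/writer shifts by one.
    ``genotype`` is a tuple of allele indexes (``0`` = ref); length 1 for
    haploid calls.
    """
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, ...] = (1,)
    allele_frequency: float | None = None
    sample_count: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"alleles must be non-empty: {self}")
        n = 1 + len(self.alts)
        if not self.genotype or any(not (0 <= g < n) for g in self.genotype):
            raise ValueError(f"genotype indexes invalid alleles: {self}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def end(self) -> int:
        """0-based half-open end of the reference span."""
        return self.pos + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_het(self) -> bool:
        return len(set(self.genotype)) > 1

    @property
    def is_hom_ref(self) -> bool:
        return set(self.genotype) == {0}

    def carried_alleles(self) -> set[str]:
        return {self.alleles[g] for g in self.genotype}

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)


class CoverageTrack:
    """Per-sequence read-depth intervals (sorted, non-overlapping, tiling).

    Intervals are ``(start, end, depth)`` with 0-based half-open spans; for
    each sequence they must tile ``[0, length)`` exactly, which makes
    min/max depth queries over a window exact.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]]):
        self.intervals: dict[str, list[tuple[int, int, float]]] = {}
        self._starts: dict[str, list[int]] = {}
        for name, ivs in intervals.items():
            ivs = sorted(ivs)
            prev_end = None
            for s, e, d in ivs:
                if e <= s or d < 0:
                    raise ValueError(f"bad coverage interval {(s, e, d)} on {name}")
                if prev_end is not None and s != prev_end:
                    raise ValueError(f"coverage intervals must tile {name}: "
                                     f"gap/overlap at {s} (prev end {prev_end})")
                prev_end = e
            self.intervals[name] = ivs
            self._starts[name] = [s for s, _, _ in ivs]

    def sequence_length(self, name: str) -> int:
        return self.intervals[name][-1][1]

    def _overlapping(self, name, start, end):
        ivs = self.intervals[name]
        i = bisect_right(self._starts[name], start) - 1
        i = max(i, 0)
        while i < len(ivs) and ivs[i][0] < end:
            s, e, d = ivs[i]
            if e > start:
                yield s, e, d
            i += 1

    def min_depth(self, name: str, start: int, end: int) -> tuple[float, int]:
        """(minimum depth, position attaining it) over the clipped window.

        The position is the midpoint of the first contiguous run of
        intervals attaining the minimum, clipped into the window, so a
        symmetric low-coverage trough reports its center.
        """
        ivs = [(max(s, start), min(e, end), d)
               for s, e, d in self._overlapping(name, start, end)]
        if not ivs:
            raise ValueError(f"window [{start},{end}) has no coverage on {name}")
        best = min(d for _, _, d in ivs)
        run_start = run_end = None
        for s, e, d in ivs:
            if d == best:
                if run_start is None:
                    run_start, run_end = s, e
                elif s == run_end:
                    run_end = e
                else:
                    break  # keep first run only
            elif run_start is not None:
                break
        return best, (run_start + run_end) // 2

    def max_depth(self, name: str, start: int, end: int) -> float:
        return max(d for _, _, d in self._overlapping(name, start, end))


@dataclass
class TilingSegment:
    """One oriented contig slice placed on a chromosome."""
    contig: str
    contig_start: int
    contig_end: int
    orientation: str  # "+" | "-"
    # projection onto the donor reference, used for gap sizing and gap fill
    donor_chrom: str | None = None
    donor_start: int | None = None
    donor_end: int | None = None
    identity: float = 1.0

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class TilingGap:
    """An estimated-size gap between two tiling segments."""
    size: int
    donor_chrom: str | None = None
    donor_start: int | None = None
    donor_end: int | None = None


class TilingPlan:
    """Ordered, oriented contig segments per chromosome with estimated gaps.

    ``plan[chrom]`` is a list alternating :class:`TilingSegment` and
    :class:`TilingGap` (never two gaps in a row, never terminal gaps).
    """

    def __init__(self, plan: dict[str, list] | None = None):
        self.plan: dict[str, list] = plan or {}

    def chromosomes(self) -> list[str]:
        return list(self.plan)

    def segments(self, chrom: str) -> list[TilingSegment]:
        return [x for x in self.plan[chrom] if isinstance(x, TilingSegment)]

    def gaps(self, chrom: str) -> list[TilingGap]:
        return [x for x in self.plan[chrom] if isinstance(x, TilingGap)]

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {chrom: [{"kind": "segment" if isinstance(it, TilingSegment)
                         else "gap", **asdict(it)} for it in items]
                for chrom, items in self.plan.items()}

    @classmethod
    def from_dict(cls, data: dict) -> "TilingPlan":
        plan: dict[str, list] = {}
        for chrom, items in data.items():
            out = []
            for it in items:
                it = dict(it)
                kind = it.pop("kind")
                out.append(TilingSegment(**it) if kind == "segment"
                           else TilingGap(**it))
            plan[chrom] = out
        return cls(plan)

    def validate(self) -> None:
        for chrom, items in self.plan.items():
            if not items:
                raise ValueError(f"empty tiling for {chrom}")
            if isinstance(items[0], TilingGap) or isinstance(items[-1], TilingGap):
                raise ValueError(f"terminal gap in tiling for {chrom}")
            for a, b in zip(items, items[1:]):
                if isinstance(a, TilingGap) and isinstance(b, TilingGap):
                    raise ValueError(f"adjacent gaps in tiling for {chrom}")
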