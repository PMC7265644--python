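"""Sequence alignment primitives.

Two layers:

* :func:`anchor_align` — a deterministic, self-contained anchor aligner
  (unique k-mer chaining).  It exists so the pipeline is fully testable
  without an external whole-genome aligner; production users may import PAF
  from any aligner instead.  Chain identity from raw anchors is a
  conservative lower bound (anchored bases only); with ``refine=True`` each
  chain is re-aligned base-level and carries exact match counts plus an
  edit path.
* :func:`global_align` — end-to-end pairwise alignment of two sequences
  (unit-cost edit-distance alignment via edlib), returning percent coverage,
  percent identity and the edit script.

Both treat sequences case-insensitively and never match through ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .model import AlignmentRecord, Assembly, revcomp

_CIG = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def _edlib_align(query: str, target: str, mode: str = "NW"):
    """edlib with a guaranteed path; both sequences uppercased."""
    res = edlib.align(query.upper(), target.upper(), task="path", mode=mode)
    if res["cigar"] is None:  # pragma: no cover - edlib always returns a path for task="path"
        raise RuntimeError("edlib returned no alignment path")
    return res


# ---------------------------------------------------------------------------
# global pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class GlobalAlignment:
    coverage: float  # percent of `a` bases aligned to a base of `b`
    identity: float  # percent of alignment columns that match
    edit_script: list[tuple[int, str]]  # cigar over a->b: = X I(extra in a) D(extra in b)
    edit_distance: int
    columns: int
    matches: int


def global_align(a: str, b: str) -> GlobalAlignment:
    """Globally align ``a`` against ``b``.

    identity is Levenshtein-based, ``(L - d) / L`` with ``L`` the longer
    sequence length and ``d`` the edit distance — this makes it symmetric
    in the arguments and invariant under joint reverse-complement, which a
    per-column definition is not (optimal paths are not unique).
    coverage = bases of ``a`` sitting in match/mismatch columns of the
    returned path / len(a) (percent), so gaps against a shorter ``b``
    reduce coverage.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    res = _edlib_align(a, b, mode="NW")
    script = parse_cigar(res["cigar"])
    d = res["editDistance"]
    L = max(len(a), len(b))
    aligned_a = sum(n for n, op in script if op in "=X")
    return GlobalAlignment(
        coverage=100.0 * aligned_a / len(a),
        identity=100.0 * (L - d) / L,
        edit_script=script,
        edit_distance=d,
        columns=L,
        matches=L - d,
    )


def locate_infix(query: str, target: str) -> tuple[int, int, int]:
    """Best infix placement of ``query`` inside ``target``.

    Returns ``(start, end, edit_distance)`` with a 0-based half-open target
    span (edlib HW mode; deterministic first-best location).
    """
    res = _edlib_align(query, target, mode="HW")
    s, e = res["locations"][0]
    return s, e + 1, res["editDistance"]


def lift_offset(query: str, target: str, offset: int) -> int | None:
    """Map a query offset to a target offset through a global alignment.

    Returns ``None`` when the query base at ``offset`` falls in a gap column
    (i.e. is deleted relative to the target); such positions have no
    single-base image.
    """
    if not (0 <= offset < len(query)):
        raise ValueError("offset outside query")
    res = _edlib_align(query, target, mode="NW")
    q = t = 0
    for n, op in parse_cigar(res["cigar"]):
        if op in "=X":
            if q <= offset < q + n:
                return t + (offset - q)
            q += n
            t += n
        elif op == "I":  # extra bases in query
            if q <= offset < q + n:
                return None
            q += n
        elif op == "D":  # extra bases in target
            t += n
    return None


# ---------------------------------------------------------------------------
# unique k-mer anchor index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Positions of k-mers that occur exactly once in the target assembly.

    K-mers containing ``N`` are skipped.  Uniqueness is assessed over the
    whole assembly (all sequences jointly), which is what makes anchor
    chains trustworthy in repeat regions.
    """

    def __init__(self, target: Assembly, k: int = 21):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.target = target
        counts: dict[str, int] = {}
        for name in target.names():
            seq = target[name].upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                counts[kmer] = counts.get(kmer, 0) + 1
        self.positions: dict[str, tuple[str, int]] = {}
        for name in target.names():
            seq = target[name].upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if counts.get(kmer) == 1:
                    self.positions[kmer] = (name, i)

    def lookup(self, kmer: str) -> tuple[str, int] | None:
        return self.positions.get(kmer)


# ---------------------------------------------------------------------------
# anchor chaining
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    tname: str
    anchors: list[tuple[int, int]]  # (qpos, tpos), co-linear

    @property
    def last(self):
        return self.anchors[-1]


def _chain_anchors(anchors, max_diag_step, max_gap):
    """Greedy co-linear chaining of (qpos, tname, tpos) anchors."""
    chains: list[_Chain] = []
    open_chains: list[_Chain] = []
    for qpos, tname, tpos in anchors:
        placed = False
        for ch in reversed(open_chains):
            lq, lt = ch.last
            if (ch.tname == tname and qpos > lq and tpos > lt
                    and abs((tpos - qpos) - (lt - lq)) <= max_diag_step
                    and qpos - lq <= max_gap and tpos - lt <= max_gap):
                ch.anchors.append((qpos, tpos))
                placed = True
                break
        if not placed:
            ch = _Chain(tname, [(qpos, tpos)])
            chains.append(ch)
            open_chains.append(ch)
            if len(open_chains) > 64:
                open_chains.pop(0)
    return chains


def _anchored_bases(anchors, k):
    """Total query bases covered by the union of anchor k-mer windows."""
    total = 0
    prev_end = -1
    for qpos, _ in anchors:
        s = max(qpos, prev_end)
        total += max(0, qpos + k - s)
        prev_end = max(prev_end, qpos + k)
    return total


def anchor_align(query: str, target: Assembly | KmerIndex, k: int = 21,
                 min_chain_anchors: int = 3, query_name: str = "query",
                 max_diag_step: int = 2000, max_gap: int = 5000,
                 refine: bool = False) -> list[AlignmentRecord]:
    """Align ``query`` to a target assembly by unique k-mer chaining.

    Anchors are k-mers unique in both query and target; co-linear anchors
    are chained greedily by diagonal.  Both strands are searched (the
    reverse strand by aligning the reverse complement).  Deterministic:
    records are sorted by (target, target start, strand).

    With ``refine=False`` matches are the anchored query bases, so identity
    is a lower bound.  With ``refine=True`` each chain span is re-aligned
    with :func:`global_align` and carries exact matches/columns.
    """
    index = target if isinstance(target, KmerIndex) else KmerIndex(target, k)
    k = index.k
    if not query:
        return []
    qlen = len(query)
    records: list[AlignmentRecord] = []

    for strand in "+-":
        q = query.upper() if strand == "+" else revcomp(query.upper())
        qcounts: dict[str, int] = {}
        for i in range(len(q) - k + 1):
            kmer = q[i:i + k]
            if "N" not in kmer:
                qcounts[kmer] = qcounts.get(kmer, 0) + 1
        anchors = []
        for i in range(len(q) - k + 1):
            kmer = q[i:i + k]
            if qcounts.get(kmer) != 1:
                continue
            hit = index.lookup(kmer)
            if hit is not None:
                anchors.append((i, hit[0], hit[1]))
        anchors.sort(key=lambda a: (a[0], a[1], a[2]))
        for ch in _chain_anchors(anchors, max_diag_step, max_gap):
            if len(ch.anchors) < min_chain_anchors:
                continue
            qs = ch.anchors[0][0]
            qe = ch.anchors[-1][0] + k
            ts = ch.anchors[0][1]
            te = ch.anchors[-1][1] + k
            if strand == "+":
                oqs, oqe = qs, qe
            else:
                oqs, oqe = qlen - qe, qlen - qs
            if refine:
                tseq = index.target[ch.tname][ts:te]
                ga = global_align(q[qs:qe], tseq)
                matches, block = ga.matches, ga.columns
            else:
                matches = _anchored_bases(ch.anchors, k)
                block = max(qe - qs, te - ts)
            records.append(AlignmentRecord(
                query_name=query_name, query_length=qlen,
                query_start=oqs, query_end=oqe, strand=strand,
                target_name=ch.tname,
                target_length=index.target.length(ch.tname),
                target_start=ts, target_end=te,
                matches=matches, block_length=block))
    records.sort(key=lambda r: (r.target_name, r.target_start, r.strand))
    return records


def best_record(records: list[AlignmentRecord]) -> AlignmentRecord | None:
    """Deterministic best hit: identity, then span, then lowest target coord."""
    if not records:
        return None
    return max(records, key=lambda r: (r.identity, r.query_span,
                                       -r.target_start,
                                       r.target_name))
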