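"""V(D)J assignment, junction decomposition and CDR-H3 extraction.

The annotation of one heavy-chain read proceeds in four stages:

1. **Segment assignment** — best-scoring local alignment against every
   germline V; the J is then aligned against the read suffix downstream of
   the accepted V.  The D is found by exact substring matching inside the
   V-to-J insert (short D segments do not support reliable scored
   alignment).

2. **Junction boundaries** — templated V and J contributions inside the
   junction window are delimited by exact base-by-base walks outward from
   the conserved anchors (forward from the V Cys codon, backward from the J
   Trp/Phe codon).  This realises the maximal-templated convention: a
   junction base that matches the adjacent germline terminus is counted as
   templated, never as an N-addition.

3. **Decomposition** — the window between the templated V end and templated
   J start is split into optional P-nucleotides, the templated D core, and
   the two N-addition stretches n1 (V-D) and n2 (D-J).

4. **CDR-H3** — the junction runs from the Cys codon through the Trp/Phe
   codon inclusive and is translated in the V reading frame; ``cdr3_aa``
   strips the two anchor residues.

Point mutations adjacent to the junction stop the templated walks early and
are therefore counted as N-additions; no somatic-hypermutation correction
is attempted (natural IgM is near-germline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .align import SegmentAlignment, local_align, ungapped_align
from .germline import GermlineSegment, GermlineSet

__all__ = [
    "AnnotationParams",
    "JunctionDecomposition",
    "Rearrangement",
    "VDJAssignment",
    "align_segment",
    "assign_vdj",
    "decompose_junction",
    "extract_cdr3",
    "annotate_read",
    "annotate_repertoire",
]

_NT = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotationParams:
    """Tunable annotation parameters.

    Scoring integers follow the conventions of :mod:`igmrep.align`.
    ``min_d_match`` is the minimum contiguous exact D match (nt) required to
    call a D.  P-nucleotides are reported only when ``call_p_nucleotides``
    is set; otherwise palindromic bases count as N-additions, matching how
    the repertoire statistics define the N burden.
    """

    match_score: int = 2
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -1
    min_v_identity: float = 0.85
    min_j_identity: float = 0.85
    min_d_match: int = 5
    max_p_len: int = 2
    call_p_nucleotides: bool = False

    def __post_init__(self) -> None:
        if self.min_d_match < 3:
            raise ValueError("min_d_match must be >= 3")
        if self.max_p_len > 3:
            raise ValueError("max_p_len must be <= 3")
        if not (0 <= self.min_v_identity <= 1 and 0 <= self.min_j_identity <= 1):
            raise ValueError("identity thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class JunctionDecomposition:
    """Ordered partition of the junction window.

    ``v_tail + p_v + n1 + d_core + n2 + p_j + j_head`` reconstructs the read
    between the V Cys anchor and the end of the J Trp/Phe codon.  When no D
    was called, ``n1`` holds the entire non-templated insert and ``n2`` /
    ``d_core`` are None (np2 undefined).
    """

    v_tail: str
    p_v: str
    n1: str
    d_core: str | None
    n2: str | None
    p_j: str
    j_head: str

    @property
    def np1(self) -> int:
        return len(self.n1)

    @property
    def np2(self) -> int | None:
        return None if self.n2 is None else len(self.n2)

    @property
    def has_d(self) -> bool:
        return self.d_core is not None

    def concatenation(self) -> str:
        return (
            self.v_tail
            + self.p_v
            + self.n1
            + (self.d_core or "")
            + (self.n2 or "")
            + self.p_j
            + self.j_head
        )


@dataclass(frozen=True)
class VDJAssignment:
    v_call: str | None
    d_call: str | None
    j_call: str | None
    v_alignment: SegmentAlignment | None
    d_alignment: SegmentAlignment | None
    j_alignment: SegmentAlignment | None
    ok: bool
    fail_reason: str | None = None
    rev_comp: bool = False
    oriented_sequence: str | None = None


@dataclass
class Rearrangement:
    """One annotated read. ``sequence`` is in V→J orientation."""

    sequence_id: str
    sequence: str
    rev_comp: bool = False
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    v_alignment: SegmentAlignment | None = None
    d_alignment: SegmentAlignment | None = None
    j_alignment: SegmentAlignment | None = None
    decomposition: JunctionDecomposition | None = None
    junction: str | None = None
    junction_aa: str | None = None
    cdr3_aa: str | None = None
    np1_length: int | None = None
    np2_length: int | None = None
    p_v_length: int | None = None
    p_j_length: int | None = None
    productive: bool = False
    annotation_ok: bool = True
    fail_reason: str | None = None

    @property
    def has_d(self) -> bool:
        return self.d_call is not None


def align_segment(
    query: str, segment: GermlineSegment, params: AnnotationParams
) -> SegmentAlignment:
    """Best local alignment of ``query`` against one germline segment."""
    if not query:
        raise ValueError("empty query")
    aln = local_align(
        query,
        segment.name,
        segment.sequence,
        match_score=params.match_score,
        mismatch_penalty=params.mismatch_penalty,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    if aln is None:
        # degenerate: no positive-scoring local alignment at all
        return SegmentAlignment(segment.name, (0, 1), (0, 1), 0, 0.0)
    return aln


_SEED_FILTER_IDENTITY = 0.9


def _best_alignment(
    query: str,
    segments: Sequence[GermlineSegment],
    params: AnnotationParams,
    query_offset: int = 0,
) -> SegmentAlignment | None:
    """Best-scoring segment alignment with a seed-filtered fast path.

    All segments are first scanned with the ungapped seed route; when a
    confident hit exists (identity >= 0.9), segments without a seeded hit
    cannot outscore it and the gapped fallback is skipped entirely.
    """
    fast: list[SegmentAlignment] = []
    for seg in segments:
        aln = ungapped_align(
            query,
            seg.name,
            seg.sequence,
            match_score=params.match_score,
            mismatch_penalty=params.mismatch_penalty,
            query_offset=query_offset,
        )
        if aln is not None:
            fast.append(aln)
    if fast:
        best_fast = min(fast, key=lambda a: a.sort_key())
        if best_fast.identity >= _SEED_FILTER_IDENTITY:
            return best_fast
    best: SegmentAlignment | None = None
    for seg in segments:
        aln = local_align(
            query,
            seg.name,
            seg.sequence,
            match_score=params.match_score,
            mismatch_penalty=params.mismatch_penalty,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            query_offset=query_offset,
        )
        if aln is None:
            continue
        if best is None or aln.sort_key() < best.sort_key():
            best = aln
    return best


def _longest_common_substring(
    insert: str, d_seq: str
) -> tuple[int, int, int] | None:
    """Longest exact shared substring: (length, insert_start, d_start).

    Leftmost-in-insert, then leftmost-in-D on ties.
    """
    best: tuple[int, int, int] | None = None
    ni, nd = len(insert), len(d_seq)
    if ni == 0 or nd == 0:
        return None
    prev = [0] * (nd + 1)
    for i in range(1, ni + 1):
        cur = [0] * (nd + 1)
        ci = insert[i - 1]
        for j in range(1, nd + 1):
            if ci == d_seq[j - 1]:
                L = prev[j - 1] + 1
                cur[j] = L
                start_i, start_j = i - L, j - L
                if (
                    best is None
                    or L > best[0]
                    or (L == best[0] and (start_i, start_j) < (best[1], best[2]))
                ):
                    best = (L, start_i, start_j)
        prev = cur
    return best


def _find_d(
    insert: str, d_segments: Sequence[GermlineSegment], min_d_match: int
) -> tuple[GermlineSegment, int, int, int] | None:
    """Best D placement in the insert: (segment, ins_start, ins_end, d_start).

    The D with the longest contiguous exact match wins; ties go to the
    lexicographically smaller name, then the leftmost insert position.
    """
    best = None
    for seg in sorted(d_segments, key=lambda s: s.name):
        hit = _longest_common_substring(insert, seg.sequence)
        if hit is None or hit[0] < min_d_match:
            continue
        L, ins_start, d_start = hit
        cand = (-L, seg.name, ins_start)
        if best is None or cand < best[0]:
            best = (cand, seg, ins_start, ins_start + L, d_start)
    if best is None:
        return None
    _, seg, a, b, d_start = best
    return seg, a, b, d_start


def assign_vdj(
    query: str, germline: GermlineSet, params: AnnotationParams | None = None
) -> VDJAssignment:
    """Assign V, J and (optionally) D segments to one read.

    A reverse-complement rescue pass is attempted when no V passes the
    identity threshold on the forward strand.  Never raises for sequence
    content; failures come back with ``ok=False`` and a reason.
    """
    params = params or AnnotationParams()
    if not query or set(query) - _NT:
        return VDJAssignment(None, None, None, None, None, None, False, "invalid_sequence")

    def _v_pass(q: str) -> SegmentAlignment | None:
        aln = _best_alignment(q, germline.of_type("V"), params)
        if aln is not None and aln.identity >= params.min_v_identity:
            return aln
        return None

    rev = False
    v_aln = _v_pass(query)
    if v_aln is None:
        rc = _revcomp(query)
        v_aln = _v_pass(rc)
        if v_aln is None:
            return VDJAssignment(None, None, None, None, None, None, False, "no_v_call")
        query, rev = rc, True

    suffix_start = v_aln.query_span[1]
    suffix = query[suffix_start:]
    j_aln = None
    if suffix:
        j_aln = _best_alignment(suffix, germline.of_type("J"), params, query_offset=suffix_start)
    if j_aln is None or j_aln.identity < params.min_j_identity:
        return VDJAssignment(
            v_aln.segment_name, None, None, v_aln, None, j_aln, False, "no_j_call",
            rev_comp=rev, oriented_sequence=query,
        )

    # D: exact search strictly between the templated V end and J start
    bounds = _junction_boundaries(query, v_aln, j_aln, germline)
    d_aln = None
    d_call = None
    if bounds is not None:
        _, v_read_end, _, j_read_start, _, _ = bounds
        insert = query[v_read_end:j_read_start]
        hit = _find_d(insert, germline.of_type("D"), params.min_d_match)
        if hit is not None:
            seg, a, b, d_start = hit
            d_call = seg.name
            d_aln = SegmentAlignment(
                segment_name=seg.name,
                query_span=(v_read_end + a, v_read_end + b),
                segment_span=(d_start, d_start + (b - a)),
                score=(b - a) * params.match_score,
                identity=1.0,
            )
    return VDJAssignment(
        v_aln.segment_name, d_call, j_aln.segment_name,
        v_aln, d_aln, j_aln, True, None, rev_comp=rev, oriented_sequence=query,
    )


def _junction_boundaries(
    query: str,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    germline: GermlineSet,
) -> tuple[int, int, int, int, int, int] | None:
    """Anchor positions and templated boundaries on the read.

    Returns (v_anchor_read, v_read_end, v_germ_end, j_read_start,
    j_germ_start, j_anchor_read) or None when an anchor is unaligned or the
    V/J windows are inconsistent.
    """
    v_seg = germline[v_aln.segment_name]
    j_seg = germline[j_aln.segment_name]
    v_anchor_read = v_aln.map_segment_pos(v_seg.anchor)
    j_anchor_read = j_aln.map_segment_pos(j_seg.anchor)
    if v_anchor_read is None or j_anchor_read is None:
        return None
    if v_anchor_read >= j_anchor_read:
        return None
    window_end = j_anchor_read + 3
    if window_end > len(query):
        return None
    # forward walk from the V Cys anchor while the read matches germline
    r, g = v_anchor_read, v_seg.anchor
    vs = v_seg.sequence
    while r < window_end and g < len(vs) and query[r] == vs[g]:
        r += 1
        g += 1
    v_read_end, v_germ_end = r, g
    # backward walk from the end of the J anchor codon
    js = j_seg.sequence
    r, g = j_anchor_read + 2, j_seg.anchor + 2
    while r >= v_read_end and g >= 0 and query[r] == js[g]:
        r -= 1
        g -= 1
    j_read_start, j_germ_start = r + 1, g + 1
    return v_anchor_read, v_read_end, v_germ_end, j_read_start, j_germ_start, j_anchor_read


def _p_prefix(insert: str, v_seq: str, v_germ_end: int, max_p: int) -> str:
    """P-nucleotides at the V end: palindromic copy of the untrimmed terminus."""
    if v_germ_end != len(v_seq):
        return ""
    best = 0
    for k in range(1, min(max_p, len(insert), len(v_seq)) + 1):
        if insert[:k] == _revcomp(v_seq[-k:]):
            best = k
    return insert[:best]


def _p_suffix(insert: str, j_seq: str, j_germ_start: int, max_p: int) -> str:
    if j_germ_start != 0:
        return ""
    best = 0
    for k in range(1, min(max_p, len(insert), len(j_seq)) + 1):
        if insert[-k:] == _revcomp(j_seq[:k]):
            best = k
    return insert[len(insert) - best :]


def decompose_junction(
    query: str,
    assignment: VDJAssignment,
    germline: GermlineSet,
    params: AnnotationParams | None = None,
) -> JunctionDecomposition:
    """Partition the junction window into templated / P / N regions.

    Requires a successful assignment.  Raises ValueError for inconsistent
    V/J geometry ("v_j_overlap") or unaligned anchors ("anchor_unaligned");
    the batch driver converts these into flagged rows.
    """
    params = params or AnnotationParams()
    if not assignment.ok:
        raise ValueError("assignment failed; nothing to decompose")
    v_aln, j_aln = assignment.v_alignment, assignment.j_alignment
    assert v_aln is not None and j_aln is not None
    if v_aln.query_span[1] > j_aln.query_span[0]:
        raise ValueError("v_j_overlap")
    bounds = _junction_boundaries(query, v_aln, j_aln, germline)
    if bounds is None:
        raise ValueError("anchor_unaligned")
    v_anchor_read, v_read_end, v_germ_end, j_read_start, j_germ_start, j_anchor_read = bounds

    v_seg = germline[v_aln.segment_name]
    j_seg = germline[j_aln.segment_name]
    v_tail = query[v_anchor_read:v_read_end]
    j_head = query[j_read_start : j_anchor_read + 3]
    insert = query[v_read_end:j_read_start]

    p_v = p_j = ""
    if params.call_p_nucleotides and insert:
        p_v = _p_prefix(insert, v_seg.sequence, v_germ_end, params.max_p_len)
        insert_rest = insert[len(p_v) :]
        p_j = _p_suffix(insert_rest, j_seg.sequence, j_germ_start, params.max_p_len)
        insert = insert_rest[: len(insert_rest) - len(p_j)]

    if assignment.d_alignment is not None:
        d_q0, d_q1 = assignment.d_alignment.query_span
        a = d_q0 - (v_read_end + len(p_v))
        b = d_q1 - (v_read_end + len(p_v))
        if 0 <= a <= b <= len(insert):
            return JunctionDecomposition(
                v_tail=v_tail, p_v=p_v,
                n1=insert[:a], d_core=insert[a:b], n2=insert[b:],
                p_j=p_j, j_head=j_head,
            )
    # no D call (or D placement swallowed by P stripping): whole insert is n1
    return JunctionDecomposition(
        v_tail=v_tail, p_v=p_v, n1=insert, d_core=None, n2=None, p_j=p_j, j_head=j_head
    )


def _translate(nt: str) -> str:
    usable = len(nt) - len(nt) % 3
    if usable <= 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def extract_cdr3(
    query: str,
    assignment: VDJAssignment,
    germline: GermlineSet,
) -> tuple[str, str, str, bool]:
    """Junction nucleotides, junction AA, CDR3 AA and productivity.

    The junction runs from the V Cys codon through the J Trp/Phe codon
    inclusive, translated in the V reading frame.  ``cdr3_aa`` strips the
    leading Cys-position and trailing Trp/Phe-position residues.  Productive
    means in-frame (length divisible by 3) and stop-free.
    """
    if not assignment.ok:
        raise ValueError("assignment failed; no junction")
    v_aln, j_aln = assignment.v_alignment, assignment.j_alignment
    assert v_aln is not None and j_aln is not None
    bounds = _junction_boundaries(query, v_aln, j_aln, germline)
    if bounds is None:
        raise ValueError("anchor_unaligned")
    v_anchor_read, _, _, _, _, j_anchor_read = bounds
    junction = query[v_anchor_read : j_anchor_read + 3]
    junction_aa = _translate(junction)
    cdr3_aa = junction_aa[1:-1] if len(junction_aa) >= 2 else ""
    productive = (len(junction) % 3 == 0) and ("*" not in junction_aa)
    return junction, junction_aa, cdr3_aa, productive


def annotate_read(
    sequence_id: str,
    sequence: str,
    germline: GermlineSet,
    params: AnnotationParams | None = None,
) -> Rearrangement:
    """Full annotation of one read; failures are flagged, never raised."""
    params = params or AnnotationParams()
    sequence = sequence.upper()
    assignment = assign_vdj(sequence, germline, params)
    if not assignment.ok:
        return Rearrangement(
            sequence_id=sequence_id,
            sequence=assignment.oriented_sequence or sequence,
            rev_comp=assignment.rev_comp,
            v_call=assignment.v_call,
            j_call=assignment.j_call,
            v_alignment=assignment.v_alignment,
            j_alignment=assignment.j_alignment,
            annotation_ok=False,
            fail_reason=assignment.fail_reason,
        )
    oriented = assignment.oriented_sequence or sequence
    try:
        decomp = decompose_junction(oriented, assignment, germline, params)
        junction, junction_aa, cdr3_aa, productive = extract_cdr3(
            oriented, assignment, germline
        )
    except ValueError as exc:
        return Rearrangement(
            sequence_id=sequence_id,
            sequence=oriented,
            rev_comp=assignment.rev_comp,
            v_call=assignment.v_call,
            d_call=assignment.d_call,
            j_call=assignment.j_call,
            v_alignment=assignment.v_alignment,
            d_alignment=assignment.d_alignment,
            j_alignment=assignment.j_alignment,
            annotation_ok=False,
            fail_reason=str(exc),
        )
    # keep d_call consistent with the decomposition (P stripping can, in
    # principle, swallow a marginal D placement)
    d_call = assignment.d_call if decomp.has_d else None
    d_aln = assignment.d_alignment if decomp.has_d else None
    return Rearrangement(
        sequence_id=sequence_id,
        sequence=oriented,
        rev_comp=assignment.rev_comp,
        v_call=assignment.v_call,
        d_call=d_call,
        j_call=assignment.j_call,
        v_alignment=assignment.v_alignment,
        d_alignment=d_aln,
        j_alignment=assignment.j_alignment,
        decomposition=decomp,
        junction=junction,
        junction_aa=junction_aa,
        cdr3_aa=cdr3_aa,
        np1_length=decomp.np1,
        np2_length=decomp.np2,
        p_v_length=len(decomp.p_v),
        p_j_length=len(decomp.p_j),
        productive=productive,
        annotation_ok=True,
    )


def _iter_reads(
    reads: str | Path | Iterable,
) -> Iterator[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        for rec in SeqIO.parse(str(reads), "fasta"):
            yield rec.id, str(rec.seq).upper()
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item[0], str(item[1]).upper()
        else:  # SeqRecord-like
            yield item.id, str(item.seq).upper()


def annotate_repertoire(
    reads: str | Path | Iterable,
    germline: GermlineSet,
    params: AnnotationParams | None = None,
) -> list[Rearrangement]:
    """Annotate a FASTA file (or iterable of (id, seq)) read by read.

    Order-preserving; unannotatable reads come back as flagged rows rather
    than being dropped.
    """
    params = params or AnnotationParams()
    return [annotate_read(rid, seq, germline, params) for rid, seq in _iter_reads(reads)]
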