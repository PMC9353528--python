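"""Local alignment of reads against germline segments.

Two routes produce a :class:`SegmentAlignment`:

* an ungapped seed-and-extend fast path (k-mer seeded diagonals, best
  contiguous-scoring run per diagonal), which resolves the vast majority of
  near-germline IgM reads, and
* a full affine-gap Smith-Waterman fallback (biotite) used whenever the
  ungapped route finds nothing convincing.

Scoring conventions: ``match_score`` > 0; ``mismatch_penalty``, ``gap_open``
and ``gap_extend`` are negative contributions; a gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

__all__ = ["SegmentAlignment", "local_align"]

_FAST_K = 11
_FAST_MIN_IDENTITY = 0.9


@dataclass(frozen=True)
class SegmentAlignment:
    """A local alignment of a query read against one germline segment.

    Spans are 0-based half-open.  ``trace`` (per-column (query, segment)
    positions, -1 for gaps) is kept only for gapped alignments; ungapped
    alignments map positions by offset arithmetic.
    """

    segment_name: str
    query_span: tuple[int, int]
    segment_span: tuple[int, int]
    score: int
    identity: float
    trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        q0, q1 = self.query_span
        s0, s1 = self.segment_span
        if not (0 <= q0 < q1 and 0 <= s0 < s1):
            raise ValueError("alignment spans must be non-empty and non-negative")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def aligned_length(self) -> int:
        return self.query_span[1] - self.query_span[0]

    def map_segment_pos(self, pos: int) -> int | None:
        """Query position aligned to germline position ``pos`` (None if gapped/outside)."""
        s0, s1 = self.segment_span
        if not s0 <= pos < s1:
            return None
        if self.trace is None:
            return self.query_span[0] + (pos - s0)
        hits = np.nonzero(self.trace[:, 1] == pos)[0]
        if hits.size == 0:
            return None
        q = int(self.trace[hits[0], 0])
        return q if q >= 0 else None

    def sort_key(self) -> tuple:
        """Across-segment tie-break: score, longer span, earlier start, name."""
        return (-self.score, -self.aligned_length, self.query_span[0], self.segment_name)


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _kadane(values: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous run: (score, start, stop). Earliest run on ties."""
    best, best_a, best_b = 0, 0, 0
    cur, cur_a = 0, 0
    for i, v in enumerate(values.tolist()):
        if cur <= 0:
            cur, cur_a = v, i
        else:
            cur += v
        if cur > best:
            best, best_a, best_b = cur, cur_a, i + 1
    return best, best_a, best_b


@lru_cache(maxsize=256)
def _kmer_index(segment: str, k: int) -> dict[str, tuple[int, ...]]:
    index: dict[str, list[int]] = {}
    for i in range(len(segment) - k + 1):
        index.setdefault(segment[i : i + k], []).append(i)
    return {kmer: tuple(pos) for kmer, pos in index.items()}


def _ungapped_best(
    query: str, segment: str, match_score: int, mismatch_penalty: int, k: int = _FAST_K
) -> tuple[int, int, int, int, float] | None:
    """Best ungapped local hit over k-mer seeded diagonals.

    Returns (score, q_start, q_end, s_start, identity) or None if no seed.
    """
    nq, ns = len(query), len(segment)
    if nq < k or ns < k:
        return None
    index = _kmer_index(segment, k)
    diags: set[int] = set()
    for i in range(nq - k + 1):
        for p in index.get(query[i : i + k], ()):
            diags.add(i - p)
    if not diags:
        return None
    qa, sa = _as_array(query), _as_array(segment)
    best: tuple | None = None
    for d in sorted(diags):
        q0 = max(0, d)
        s0 = q0 - d
        L = min(nq - q0, ns - s0)
        if L <= 0:
            continue
        eq = qa[q0 : q0 + L] == sa[s0 : s0 + L]
        vals = np.where(eq, match_score, mismatch_penalty)
        score, a, b = _kadane(vals)
        if b <= a:
            continue
        ident = float(eq[a:b].mean())
        cand = (score, -(b - a), q0 + a, ident, q0 + b, s0 + a)
        if best is None or (cand[0], cand[1], -cand[2]) > (best[0], best[1], -best[2]):
            best = cand
    if best is None:
        return None
    score, neg_len, q_start, ident, q_end, s_start = best
    return score, q_start, q_end, s_start, ident


@lru_cache(maxsize=8)
def _subst_matrix(match_score: int, mismatch_penalty: int) -> SubstitutionMatrix:
    alph = NucleotideSequence.alphabet_unamb
    n = len(alph)
    scores = np.full((n, n), mismatch_penalty, dtype=np.int32)
    np.fill_diagonal(scores, match_score)
    return SubstitutionMatrix(alph, alph, scores)


def _sw_align(
    query: str,
    segment: str,
    match_score: int,
    mismatch_penalty: int,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, tuple[int, int], tuple[int, int], float, np.ndarray] | None:
    matrix = _subst_matrix(match_score, mismatch_penalty)
    alns = align_optimal(
        NucleotideSequence(query),
        NucleotideSequence(segment),
        matrix,
        gap_penalty=(gap_open, gap_extend),
        local=True,
        max_number=1,
    )
    if not alns:
        return None
    aln = alns[0]
    trace = aln.trace
    q_cols = trace[:, 0]
    s_cols = trace[:, 1]
    q_valid = q_cols[q_cols >= 0]
    s_valid = s_cols[s_cols >= 0]
    if q_valid.size == 0 or s_valid.size == 0:
        return None
    both = (q_cols >= 0) & (s_cols >= 0)
    qa, sa = _as_array(query), _as_array(segment)
    matches = int(np.sum(qa[q_cols[both]] == sa[s_cols[both]]))
    identity = matches / len(trace)
    q_span = (int(q_valid.min()), int(q_valid.max()) + 1)
    s_span = (int(s_valid.min()), int(s_valid.max()) + 1)
    return int(aln.score), q_span, s_span, identity, trace


def ungapped_align(
    query: str,
    segment_name: str,
    segment_seq: str,
    match_score: int = 2,
    mismatch_penalty: int = -2,
    query_offset: int = 0,
) -> SegmentAlignment | None:
    """Ungapped seed-and-extend alignment only; None when no seeded hit."""
    if not query:
        raise ValueError("empty query")
    fast = _ungapped_best(query, segment_seq, match_score, mismatch_penalty)
    if fast is None:
        return None
    score, q0, q1, s0, ident = fast
    return SegmentAlignment(
        segment_name=segment_name,
        query_span=(q0 + query_offset, q1 + query_offset),
        segment_span=(s0, s0 + (q1 - q0)),
        score=score,
        identity=ident,
    )


def local_align(
    query: str,
    segment_name: str,
    segment_seq: str,
    match_score: int = 2,
    mismatch_penalty: int = -2,
    gap_open: int = -5,
    gap_extend: int = -1,
    query_offset: int = 0,
) -> SegmentAlignment | None:
    """Best local alignment of ``query`` against one germline segment.

    ``query_offset`` shifts reported query coordinates (used when aligning a
    read suffix).  Returns None only when not even the gapped route finds a
    positive-scoring alignment.
    """
    if not query:
        raise ValueError("empty query")
    fast = _ungapped_best(query, segment_seq, match_score, mismatch_penalty)
    if fast is not None:
        score, q0, q1, s0, ident = fast
        if ident >= _FAST_MIN_IDENTITY:
            return SegmentAlignment(
                segment_name=segment_name,
                query_span=(q0 + query_offset, q1 + query_offset),
                segment_span=(s0, s0 + (q1 - q0)),
                score=score,
                identity=ident,
            )
    sw = _sw_align(query, segment_seq, match_score, mismatch_penalty, gap_open, gap_extend)
    if sw is None:
        return None
    score, q_span, s_span, identity, trace = sw
    if score <= 0:
        return None
    trace = trace.copy()
    trace[trace[:, 0] >= 0, 0] += query_offset
    gapped = bool(np.any(trace < 0))
    return SegmentAlignment(
        segment_name=segment_name,
        query_span=(q_span[0] + query_offset, q_span[1] + query_offset),
        segment_span=s_span,
        score=score,
        identity=identity,
        trace=trace if gapped else None,
    )
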