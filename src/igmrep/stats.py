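"""Per-repertoire summaries: junctional N-addition statistics, V/D/J family
usage, and CDR-H3 clonality.

The junctional category of a sequence places it in one of four cells by
whether it carries N-additions at the V-D junction (np1), the D-J junction
(np2), both, or neither.  A sequence is *eligible* for these statistics when
it annotated cleanly, is productive, and carries a D call (both junctions
must exist); the eligibility filters are exposed as switches.

Clonality is measured as the replicate fraction: the proportion of eligible
sequences whose exact CDR-H3 amino acid string occurs two or more times
within the repertoire.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .annotate import Rearrangement
from .germline import GermlineSet, family_of

__all__ = [
    "CATEGORIES",
    "JunctionCategory",
    "RepertoireSummary",
    "junction_category",
    "summarize_repertoire",
    "usage_table",
    "cdr3_hamming",
]

JunctionCategory = Literal["both_zero", "vd_only", "dj_only", "both_ge1"]
CATEGORIES: tuple[JunctionCategory, ...] = ("both_zero", "vd_only", "dj_only", "both_ge1")


def junction_category(r: Rearrangement) -> JunctionCategory:
    """Four-way junctional category of a productive, D-called rearrangement."""
    if not r.annotation_ok or not r.has_d or r.np1_length is None or r.np2_length is None:
        raise ValueError("ineligible")
    np1, np2 = r.np1_length, r.np2_length
    if np1 == 0 and np2 == 0:
        return "both_zero"
    if np1 >= 1 and np2 >= 1:
        return "both_ge1"
    if np1 >= 1:
        return "vd_only"
    return "dj_only"


def _eligible(
    rearrangements: Iterable[Rearrangement],
    include_unproductive: bool,
    include_no_d: bool,
) -> list[Rearrangement]:
    out = []
    for r in rearrangements:
        if not r.annotation_ok:
            continue
        if not include_unproductive and not r.productive:
            continue
        if not include_no_d and not r.has_d:
            continue
        out.append(r)
    return out


@dataclass
class RepertoireSummary:
    """All per-repertoire statistics over one set of rearrangements."""

    name: str
    n_total: int
    n_annotated: int
    n_productive: int
    n_no_d: int
    n_eligible: int
    category_counts: dict[str, int]
    category_freqs: dict[str, float]  # percentages of eligible
    mean_np1: float | None
    mean_np2: float | None
    mean_sum: float | None
    usage: dict[str, dict[str, float]]  # segment type -> family -> fraction
    replicate_fraction: float | None
    clone_table: list[tuple[str, int]]  # cdr3_aa, count; descending

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_total": self.n_total,
            "n_annotated": self.n_annotated,
            "n_productive": self.n_productive,
            "n_no_d": self.n_no_d,
            "n_eligible": self.n_eligible,
            "category_counts": dict(self.category_counts),
            "category_freqs": dict(self.category_freqs),
            "mean_np1": self.mean_np1,
            "mean_np2": self.mean_np2,
            "mean_sum": self.mean_sum,
            "usage": {st: dict(t) for st, t in self.usage.items()},
            "replicate_fraction": self.replicate_fraction,
            "clone_table": [list(x) for x in self.clone_table],
        }


def summarize_repertoire(
    rearrangements: Sequence[Rearrangement],
    name: str = "repertoire",
    germline: GermlineSet | None = None,
    include_unproductive: bool = False,
    include_no_d: bool = False,
) -> RepertoireSummary:
    """Compute category, N-addition, usage and clonality statistics.

    Eligibility defaults to productive AND D-called.  With ``include_no_d``
    usage and clonality extend to no-D reads, but category counts and np2
    means remain restricted to D-called reads (both junctions must exist).
    """
    n_total = len(rearrangements)
    annotated = [r for r in rearrangements if r.annotation_ok]
    eligible = _eligible(rearrangements, include_unproductive, include_no_d)
    with_d = [r for r in eligible if r.has_d]

    cat_counts = {c: 0 for c in CATEGORIES}
    for r in with_d:
        cat_counts[junction_category(r)] += 1
    n_cat = sum(cat_counts.values())
    cat_freqs = {
        c: (100.0 * k / n_cat if n_cat else 0.0) for c, k in cat_counts.items()
    }

    if with_d:
        np1s = [r.np1_length for r in with_d]
        np2s = [r.np2_length for r in with_d]
        mean_np1 = sum(np1s) / len(np1s)
        mean_np2 = sum(np2s) / len(np2s)
        mean_sum = mean_np1 + mean_np2
    else:
        mean_np1 = mean_np2 = mean_sum = None

    usage = {
        st: usage_table(eligible, st, germline=germline) for st in ("V", "D", "J")
    }

    cdr3s = [r.cdr3_aa for r in eligible if r.cdr3_aa]
    counts = Counter(cdr3s)
    if cdr3s:
        replicated = sum(k for k in counts.values() if k >= 2)
        replicate_fraction = replicated / len(cdr3s)
    else:
        replicate_fraction = None
    clone_table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    return RepertoireSummary(
        name=name,
        n_total=n_total,
        n_annotated=len(annotated),
        n_productive=sum(r.productive for r in annotated),
        n_no_d=sum(not r.has_d for r in annotated),
        n_eligible=len(with_d) if not include_no_d else len(eligible),
        category_counts=cat_counts,
        category_freqs=cat_freqs,
        mean_np1=mean_np1,
        mean_np2=mean_np2,
        mean_sum=mean_sum,
        usage=usage,
        replicate_fraction=replicate_fraction,
        clone_table=clone_table,
    )


def usage_table(
    rearrangements: Sequence[Rearrangement],
    segment_type: Literal["V", "D", "J"],
    germline: GermlineSet | None = None,
) -> dict[str, float]:
    """Family usage frequencies (fractions summing to 1) for one segment type.

    For D the denominator is D-called reads only.  Families present in the
    germline vocabulary but unused appear with frequency 0.
    """
    if segment_type not in ("V", "D", "J"):
        raise ValueError(f"segment_type must be V, D or J, got {segment_type!r}")
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_type]
    calls = [getattr(r, attr) for r in rearrangements if getattr(r, attr)]
    counts = Counter(family_of(c) for c in calls)
    table: dict[str, float] = {}
    if germline is not None:
        table = {fam: 0.0 for fam in germline.families(segment_type)}
    total = sum(counts.values())
    for fam, k in counts.items():
        table[fam] = k / total if total else 0.0
    return dict(sorted(table.items()))


def cdr3_hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length CDR-H3 amino acid strings."""
    if not a or not b:
        raise ValueError("empty CDR3 string")
    if len(a) != len(b):
        raise ValueError(f"unequal lengths ({len(a)} vs {len(b)}); no alignment attempted")
    return sum(x != y for x, y in zip(a, b))
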