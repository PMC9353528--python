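"""Between-repertoire statistics.

Three comparisons mirror how B-1 subset repertoires are contrasted:

* a 2xK Pearson chi-square (no continuity correction) on the junctional
  category distributions of two repertoires,
* a two-sided Mann-Whitney U test on per-sequence N-addition counts, exact
  when samples are small and tie-free, tie-corrected normal approximation
  otherwise, and
* per-family 2x2 Fisher exact tests (uses vs non-uses) with
  Benjamini-Hochberg adjustment across the families of one segment type.
  Both raw and adjusted p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotate import Rearrangement
from .germline import GermlineSet, family_of
from .stats import CATEGORIES, junction_category, _eligible

__all__ = [
    "ContingencyResult",
    "RankTestResult",
    "FamilyComparison",
    "chi2_contingency",
    "mann_whitney",
    "compare_family_usage",
    "category_counts_vector",
    "n_addition_sums",
]

_EXACT_MAX_N = 16


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    dropped_categories: tuple[int, ...] = ()


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: Literal["exact", "normal-approximation"]


@dataclass
class FamilyComparison:
    family: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # (uses, non-uses) per group
    p_raw: float
    p_adjusted: float


def chi2_contingency(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> ContingencyResult:
    """Pearson chi-square on a 2xK table of category counts.

    Categories empty in both groups are dropped with the degrees of freedom
    reduced accordingly (recorded in ``dropped_categories``).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts_a and counts_b must be equal-length vectors")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each group must have a positive total")
    obs = np.vstack([a, b])
    col_totals = obs.sum(axis=0)
    dropped = tuple(int(i) for i in np.nonzero(col_totals == 0)[0])
    keep = col_totals > 0
    obs_kept = obs[:, keep]
    if obs_kept.shape[1] < 2:
        raise ValueError("fewer than two non-empty categories")
    stat, p, df, expected = sps.chi2_contingency(obs_kept, correction=False)
    return ContingencyResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        observed=obs_kept,
        expected=expected,
        dropped_categories=dropped,
    )


def mann_whitney(xs: Sequence[float], ys: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U on two samples (e.g. per-sequence N sums).

    Exact null enumeration when n1 + n2 <= 16 with no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    xs = list(xs)
    ys = list(ys)
    if not xs or not ys:
        raise ValueError("empty sample")
    n1, n2 = len(xs), len(ys)
    no_ties = len(set(xs) | set(ys)) == n1 + n2
    if n1 + n2 <= _EXACT_MAX_N and no_ties:
        res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
        method: Literal["exact", "normal-approximation"] = "exact"
    else:
        res = sps.mannwhitneyu(
            xs, ys, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation"
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=n1,
        n2=n2,
        method=method,
    )


def category_counts_vector(
    rearrangements: Sequence[Rearrangement],
    include_unproductive: bool = False,
) -> list[int]:
    """Counts over the four junctional categories, in CATEGORIES order."""
    eligible = _eligible(rearrangements, include_unproductive, include_no_d=False)
    counts = {c: 0 for c in CATEGORIES}
    for r in eligible:
        counts[junction_category(r)] += 1
    return [counts[c] for c in CATEGORIES]


def n_addition_sums(
    rearrangements: Sequence[Rearrangement],
    include_unproductive: bool = False,
) -> list[int]:
    """Per-sequence np1 + np2 over eligible (productive, D-called) reads."""
    eligible = _eligible(rearrangements, include_unproductive, include_no_d=False)
    return [r.np1_length + r.np2_length for r in eligible]


def compare_family_usage(
    reps_a: Sequence[Rearrangement],
    reps_b: Sequence[Rearrangement],
    segment_type: Literal["V", "D", "J"],
    germline: GermlineSet | None = None,
    include_unproductive: bool = False,
) -> list[FamilyComparison]:
    """Per-family Fisher exact comparisons with BH adjustment.

    Each family contributes a 2x2 table (uses vs non-uses in each group)
    over D-called productive reads; families unused in both groups are
    skipped.  When a germline is given, observed families outside its
    vocabulary raise a mismatch error.
    """
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_type]
    groups = []
    for reps in (reps_a, reps_b):
        eligible = _eligible(reps, include_unproductive, include_no_d=False)
        fams = [family_of(getattr(r, attr)) for r in eligible if getattr(r, attr)]
        groups.append(fams)
    vocab = sorted(set(groups[0]) | set(groups[1]))
    if germline is not None:
        allowed = set(germline.families(segment_type))
        extra = set(vocab) - allowed
        if extra:
            raise ValueError(
                f"family vocabulary mismatch: {sorted(extra)} not in germline"
            )
        vocab = sorted(allowed & set(vocab))
    n_a, n_b = len(groups[0]), len(groups[1])
    results = []
    for fam in vocab:
        ua = groups[0].count(fam)
        ub = groups[1].count(fam)
        if ua == 0 and ub == 0:
            continue
        table = [[ua, n_a - ua], [ub, n_b - ub]]
        _, p = sps.fisher_exact(table, alternative="two-sided")
        results.append((fam, ((ua, n_a - ua), (ub, n_b - ub)), float(p)))
    if not results:
        return []
    p_raw = [r[2] for r in results]
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return [
        FamilyComparison(family=fam, counts=counts, p_raw=p, p_adjusted=float(pa))
        for (fam, counts, p), pa in zip(results, p_adj)
    ]
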