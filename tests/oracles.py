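"""Independent brute-force oracles used only by the tests.

These deliberately re-derive expected values from first principles
(exhaustive dynamic programming, full permutation enumeration, direct
formulas) without touching the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations


def dp_local_score(
    q: str, s: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> int:
    """Affine-gap Smith-Waterman score by explicit Gotoh recursion.

    Gap of length L costs gap_open + (L - 1) * gap_extend (negative values).
    """
    n, m = len(q), len(s)
    NEG = -(10**9)
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (deletion from q)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def chi2_direct(counts_a, counts_b) -> float:
    """Pearson chi-square by direct summation of (O-E)^2/E over all cells."""
    rows = [list(map(float, counts_a)), list(map(float, counts_b))]
    row_tot = [sum(r) for r in rows]
    col_tot = [rows[0][j] + rows[1][j] for j in range(len(rows[0]))]
    total = sum(row_tot)
    stat = 0.0
    for i in range(2):
        for j in range(len(rows[0])):
            e = row_tot[i] * col_tot[j] / total
            stat += (rows[i][j] - e) ** 2 / e
    return stat


def mw_enumeration(xs, ys) -> tuple[float, float]:
    """Mann-Whitney U and exact two-sided p by full labeling enumeration."""
    xs, ys = list(xs), list(ys)
    n1, n2 = len(xs), len(ys)
    pooled = xs + ys

    def u_of(group_idx: tuple[int, ...]) -> float:
        gx = [pooled[i] for i in group_idx]
        gy = [pooled[i] for i in range(n1 + n2) if i not in group_idx]
        u = 0.0
        for a in gx:
            for b in gy:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = 0.0
    for a in xs:
        for b in ys:
            u_obs += (a > b) + 0.5 * (a == b)
    us = [u_of(idx) for idx in combinations(range(n1 + n2), n1)]
    total = len(us)
    le = sum(u <= u_obs for u in us)
    ge = sum(u >= u_obs for u in us)
    p = min(1.0, 2 * min(le, ge) / total)
    return u_obs, p


def bh_stepup(p_values):
    """Benjamini-Hochberg adjusted p-values by the step-up rule."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p_values[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def min_np_partition(
    window: str,
    v_tail_germ: str,
    j_head_germ: str,
    d_seqs: dict[str, str],
    min_d_match: int,
) -> int | None:
    """Minimum achievable np1+np2 over all exact-templated partitions.

    Enumerates every consistent choice of templated V prefix (matching
    ``v_tail_germ`` from its start), templated J suffix (matching the end
    of ``j_head_germ``), and exact D placement of length >= min_d_match in
    the remaining middle.  Returns None when no D placement exists for any
    choice.
    """
    n = len(window)
    v_opts = [
        l
        for l in range(min(n, len(v_tail_germ)) + 1)
        if window[:l] == v_tail_germ[:l]
    ]
    j_opts = [
        l
        for l in range(min(n, len(j_head_germ)) + 1)
        if l == 0 or window[n - l :] == j_head_germ[len(j_head_germ) - l :]
    ]
    best = None
    for lv in v_opts:
        for lj in j_opts:
            if lv + lj > n:
                continue
            middle = window[lv : n - lj]
            for d in d_seqs.values():
                for L in range(len(middle), min_d_match - 1, -1):
                    found = False
                    for start in range(0, len(middle) - L + 1):
                        if middle[start : start + L] in d:
                            found = True
                            break
                    if found:
                        np_total = len(middle) - L
                        if best is None or np_total < best:
                            best = np_total
                        break
    return best
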