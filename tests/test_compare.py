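import math

import numpy as np
import pytest

from igmrep.annotate import Rearrangement
from igmrep.compare import (
    category_counts_vector,
    chi2_contingency,
    compare_family_usage,
    mann_whitney,
    n_addition_sums,
)

from .oracles import bh_stepup, chi2_direct, mw_enumeration


class TestChi2:
    def test_identical_distributions_give_zero(self):
        res = chi2_contingency((10, 10, 10, 10), (10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 3

    def test_matches_direct_formula_on_fixed_tables(self):
        a, b = (46, 3, 1, 0), (18, 9, 6, 14)
        res = chi2_contingency(a, b)
        assert res.statistic == pytest.approx(chi2_direct(a, b), abs=1e-9)
        assert res.df == 3

    def test_label_swap_invariance_and_count_scaling(self):
        a, b = (20, 5, 3, 2), (8, 9, 6, 7)
        r1 = chi2_contingency(a, b)
        r2 = chi2_contingency(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        k = 3
        r3 = chi2_contingency(tuple(k * x for x in a), tuple(k * x for x in b))
        assert r3.statistic == pytest.approx(k * r1.statistic)

    def test_empty_category_dropped_with_df_reduced(self):
        res = chi2_contingency((10, 0, 5, 5), (8, 0, 6, 4))
        assert res.dropped_categories == (1,)
        assert res.df == 2

    def test_zero_group_total_rejected(self):
        with pytest.raises(ValueError):
            chi2_contingency((0, 0, 0, 0), (1, 2, 3, 4))

    def test_type_i_error_within_binomial_bounds(self):
        """Null calibration: both groups drawn from one category distribution."""
        rng = np.random.default_rng(20260926)
        probs = (0.4, 0.3, 0.2, 0.1)
        alpha = 0.05
        n_sims = 1000
        rejections = 0
        for _ in range(n_sims):
            a = rng.multinomial(100, probs)
            b = rng.multinomial(100, probs)
            if chi2_contingency(a, b).p_value < alpha:
                rejections += 1
        rate = rejections / n_sims
        half_width = 2.576 * math.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) <= half_width


class TestMannWhitney:
    def test_complete_separation_small_sample_exact(self):
        res = mann_whitney((0, 1, 2), (4, 5, 6))
        assert res.method == "exact"
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)

    def test_exact_mode_equals_full_enumeration_small_samples(self):
        rng = np.random.default_rng(42)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                xs = list(rng.permutation(100)[:n1].astype(float))
                ys = list(rng.permutation(1000)[100 : 100 + n2].astype(float))
                if len(set(xs) | set(ys)) < n1 + n2:
                    continue
                res = mann_whitney(xs, ys)
                u_ref, p_ref = mw_enumeration(xs, ys)
                assert res.method == "exact"
                assert res.u_statistic == pytest.approx(u_ref)
                assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_identical_samples_central_u_high_p(self):
        xs = [1, 1, 2, 2, 3, 3, 4, 4, 5]
        res = mann_whitney(xs, list(xs))
        assert res.u_statistic == pytest.approx(len(xs) ** 2 / 2)
        assert res.p_value >= 0.99
        assert res.method == "normal-approximation"  # ties force approximation

    def test_exact_and_approximate_agree_moderate_n(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        xs = list(rng.normal(size=8))
        ys = list(rng.normal(size=8))
        exact = mann_whitney(xs, ys)
        assert exact.method == "exact"
        approx_p = mannwhitneyu(
            xs, ys, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(exact.p_value - approx_p) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1, 2])

    def test_u_bounded_by_n1_n2(self, preset_runs):
        xs = n_addition_sums(preset_runs["perc_b1a"][1])
        ys = n_addition_sums(preset_runs["spleen_b1b"][1])
        res = mann_whitney(xs, ys)
        assert 0 <= res.u_statistic <= res.n1 * res.n2
        assert res.p_value < 1e-4  # the extreme presets separate decisively


def _usage_reads(families, prefix, d="IGHD2*01"):
    out = []
    for i, fam in enumerate(families):
        out.append(
            Rearrangement(
                sequence_id=f"{prefix}{i}",
                sequence="ACGT",
                v_call=f"IGH{fam}",
                d_call=d,
                j_call="IGHJ1*01",
                cdr3_aa="AR",
                np1_length=0,
                np2_length=0,
                productive=True,
                annotation_ok=True,
            )
        )
    return out


class TestFamilyUsage:
    def test_identical_usage_gives_p_one(self):
        a = _usage_reads(["V1-1*01"] * 10 + ["V12-3*01"] * 10, "a")
        b = _usage_reads(["V1-1*01"] * 10 + ["V12-3*01"] * 10, "b")
        for fc in compare_family_usage(a, b, "V"):
            assert fc.p_raw == pytest.approx(1.0)

    def test_complete_separation_matches_hypergeometric_tail(self):
        a = _usage_reads(["V1-1*01"] * 20, "a")
        b = _usage_reads(["V12-3*01"] * 20, "b")
        res = {fc.family: fc for fc in compare_family_usage(a, b, "V")}
        expected = min(1.0, 2.0 / math.comb(40, 20))
        assert res["VH1"].p_raw == pytest.approx(expected, rel=1e-9)

    def test_bh_stepup_oracle_hand_example(self):
        # step-up on (0.001, 0.02, 0.8): 0.001*3/1, 0.02*3/2, 0.8*3/3
        assert bh_stepup([0.001, 0.02, 0.8]) == pytest.approx([0.003, 0.03, 0.8])

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(11)
        fams = ["V1-1*01", "V2-1*01", "V12-3*01", "V14-1*01"]
        a = _usage_reads(list(rng.choice(fams, 60)), "a")
        b = _usage_reads(list(rng.choice(fams[:2], 60)), "b")
        comps = compare_family_usage(a, b, "V")
        p_raw = [fc.p_raw for fc in comps]
        expected = bh_stepup(p_raw)
        for fc, e in zip(comps, expected):
            assert fc.p_adjusted == pytest.approx(e, rel=1e-9)
            assert fc.p_adjusted >= fc.p_raw - 1e-12

    def test_vocabulary_mismatch_rejected(self, germline):
        a = _usage_reads(["V99-1*01"] * 5, "a")
        b = _usage_reads(["V1-1*01"] * 5, "b")
        with pytest.raises(ValueError, match="vocabulary"):
            compare_family_usage(a, b, "V", germline=germline)


def test_category_counts_vector_ordering(preset_runs):
    _, anns = preset_runs["perc_b1a"]
    counts = category_counts_vector(anns)
    assert len(counts) == 4
    assert counts[0] == max(counts)  # both_zero dominates the PerC B-1a preset
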