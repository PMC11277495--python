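"""The group-comparison battery against independent textbook computations."""

import math

import numpy as np
import pytest
import scipy.stats as st

from flysleep.group_stats import (
    dunn_posthoc,
    multi_group_compare,
    normality_screen,
    rhythmicity_frequency_test,
    summarize,
    two_group_compare,
)


class TestSummarize:
    def test_basic(self):
        s = summarize([1, 2, 3], "wt", "f", "tst_min")
        assert (s.mean, s.sd, s.median) == (2.0, 1.0, 2.0)
        assert (s.min, s.max, s.n) == (1.0, 3.0, 3)

    def test_single_value(self):
        s = summarize([4.2], "wt", "f", "tst_min")
        assert s.mean == s.median == s.min == s.max == 4.2
        assert math.isnan(s.sd)

    def test_nan_dropped(self):
        s = summarize([1.0, np.nan, 3.0], "wt", "f", "x")
        assert s.n == 2 and s.mean == 2.0

    def test_order_invariant(self, rng):
        v = rng.normal(size=20)
        a = summarize(v, "g", "s", "p")
        b = summarize(v[::-1], "g", "s", "p")
        for f in ("mean", "sd", "median", "min", "max"):
            assert getattr(a, f) == pytest.approx(getattr(b, f))


class TestChiSquare:
    def test_matches_textbook_formula(self, rng):
        """Statistic equals the direct sum of (O-E)^2/E over the table."""
        for _ in range(50):
            table = rng.integers(5, 60, size=(2, 3))
            res = rhythmicity_frequency_test(table)
            total = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / total
            oracle = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(oracle)

    def test_identical_proportions_not_significant(self):
        res = rhythmicity_frequency_test(np.array([[40, 40], [10, 10]]))
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_observed_group_contrast_significant(self):
        # 48/50 vs 31/50 rhythmic
        res = rhythmicity_frequency_test(np.array([[48, 31], [2, 19]]))
        assert res.significant
        assert res.p_value < 0.0001

    def test_rejects_negative_or_float(self):
        with pytest.raises(ValueError):
            rhythmicity_frequency_test(np.array([[1.5, 2.0], [3.0, 4.0]]))
        with pytest.raises(ValueError):
            rhythmicity_frequency_test(np.array([[-1, 2], [3, 4]]))


class TestKruskalDunn:
    def test_h_statistic_matches_rank_arithmetic(self):
        """H from scipy equals the direct rank-sum formula (no ties)."""
        groups = {
            "a": [1.0, 5.0, 8.0],
            "b": [2.0, 4.0, 9.0, 11.0],
            "c": [3.0, 6.0, 7.0, 10.0, 12.0],
        }
        results = multi_group_compare(groups)
        omnibus = results[0]
        pooled = np.concatenate(list(groups.values()))
        ranks = st.rankdata(pooled)
        n = len(pooled)
        idx = 0
        h = 0.0
        for g in groups.values():
            r = ranks[idx : idx + len(g)]
            h += r.sum() ** 2 / len(g)
            idx += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        assert omnibus.statistic == pytest.approx(h)

    def test_identical_groups_not_significant(self):
        groups = {"a": [1.0, 2.0, 3.0]} | {
            k: [1.0, 2.0, 3.0] for k in ("b", "c")
        }
        results = multi_group_compare(groups)
        assert not results[0].significant

    def test_shifted_group_flagged_only_in_its_contrasts(self, rng):
        base = rng.normal(0, 1, size=30)
        groups = {
            "a": base,
            "b": rng.normal(0, 1, size=30),
            "c": rng.normal(20, 1, size=30),
        }
        results = multi_group_compare(groups)
        dunn = {r.groups: r for r in results[1:]}
        assert dunn[("a", "c")].significant
        assert dunn[("b", "c")].significant
        assert not dunn[("a", "b")].significant

    def test_adjusted_p_never_below_raw(self, rng):
        groups = {k: rng.normal(i * 0.3, 1, size=12) for i, k in enumerate("abcd")}
        for r in dunn_posthoc(groups):
            assert r.p_adjusted >= r.p_value - 1e-15
            assert r.p_adjusted <= 1.0

    def test_dunn_z_hand_computed(self):
        """Tiny example checked by explicit midrank arithmetic."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = dunn_posthoc(groups)[0]
        # ranks 1..6: mean ranks 2 and 5; S^2 = 6*7/12 = 3.5 (no ties)
        z = (2.0 - 5.0) / math.sqrt(3.5 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(z)
        assert res.p_value == pytest.approx(2 * st.norm.sf(abs(z)))

    def test_label_order_invariance(self, rng):
        a, b, c = (rng.normal(size=15) for _ in range(3))
        r1 = multi_group_compare({"a": a, "b": b, "c": c})[0]
        r2 = multi_group_compare({"c": c, "a": a, "b": b})[0]
        assert r1.statistic == pytest.approx(r2.statistic)


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        res = two_group_compare([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        # 2 / C(10,5) = 2 * 5!5!/10!
        assert res.p_value == pytest.approx(2 * (120 * 120) / 3628800)
        assert res.note == "exact"

    def test_identical_samples_not_significant(self, rng):
        v = rng.normal(size=30)
        res = two_group_compare(v, v + rng.normal(0, 1e-12, 30))
        assert res.p_value > 0.9
        assert not res.significant

    def test_u_identity(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=13)
        u_ab = two_group_compare(a, b).statistic
        u_ba = two_group_compare(b, a).statistic
        assert u_ab + u_ba == pytest.approx(9 * 13)

    def test_ties_fall_back_to_midrank_approximation(self):
        res = two_group_compare([1, 1, 2, 2], [2, 3, 3, 4])
        assert res.note == "asymptotic"


class TestNormalityScreen:
    def test_calibration_on_normal_samples(self, rng):
        reps, n = 400, 50
        sw_rej = ks_rej = 0
        for _ in range(reps):
            res = normality_screen(rng.normal(size=n))
            sw_rej += res[0].significant
            ks_rej += res[1].significant
        assert 0.02 <= sw_rej / reps <= 0.09
        assert 0.02 <= ks_rej / reps <= 0.09

    def test_skewed_sample_rejected(self, rng):
        rejections = sum(
            normality_screen(rng.exponential(size=50))[0].significant
            for _ in range(50)
        )
        assert rejections >= 45

    def test_constant_sample_degenerate(self):
        res = normality_screen([2.0, 2.0, 2.0, 2.0])
        assert all("degenerate" in r.note for r in res)
        assert not any(r.significant for r in res)

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])
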