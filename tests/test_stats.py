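import math

import numpy as np
import pytest
from scipy import stats as sps

from rhodoscan.stats import (
    bh_adjust,
    fit_tuning_trend,
    paired_t_one_sided,
    spearman_fdr,
    wilcoxon_signed_rank_paired,
)
import pandas as pd


class TestPairedT:
    def test_equal_vectors_give_half(self):
        r = paired_t_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert r.statistic == 0.0
        assert r.p_value == 0.5
        assert r.degenerate

    def test_constant_positive_difference_degenerate(self):
        r = paired_t_one_sided([2.0, 3.0], [1.0, 2.0], "greater")
        assert r.p_value == 0.0
        assert r.degenerate
        assert paired_t_one_sided([2.0, 3.0], [1.0, 2.0], "less").p_value == 1.0

    def test_textbook_vector_matches_reference(self):
        x = np.array([1.1, 1.3, 0.9, 1.2])
        y = np.ones(4)
        mine = paired_t_one_sided(x, y, "greater")
        ref = sps.ttest_rel(x, y, alternative="greater")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_random_vectors_match_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            x = rng.normal(0.2, 1.0, n)
            y = rng.normal(0.0, 1.0, n)
            for d in ("greater", "less"):
                mine = paired_t_one_sided(x, y, d)
                ref = sps.ttest_rel(x, y, alternative=d)
                assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_one_sided([1.0], [2.0], "greater")
        with pytest.raises(ValueError):
            paired_t_one_sided([1.0, 2.0], [1.0, 2.0], "sideways")


class TestWilcoxon:
    def test_five_positive_pairs_exact(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.5, 1.4, 2.3, 3.2, 4.1]  # distinct positive differences
        r = wilcoxon_signed_rank_paired(x, y, "greater")
        assert r.p_value == pytest.approx(1 / 32, abs=1e-12)
        assert r.n_pairs == 5

    def test_identical_vectors_undefined(self):
        r = wilcoxon_signed_rank_paired([1.0, 2.0], [1.0, 2.0], "greater")
        assert r.degenerate
        assert math.isnan(r.p_value)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(0.3, 1.0, 12)
            y = rng.normal(0.0, 1.0, 12)
            a = wilcoxon_signed_rank_paired(x, y, "greater").p_value
            b = wilcoxon_signed_rank_paired(y, x, "less").p_value
            assert a == pytest.approx(b, abs=1e-12)

    def test_exact_matches_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n = int(rng.integers(5, 22))
            x = rng.normal(0.3, 1.0, n)
            y = rng.normal(0.0, 1.0, n)
            for d in ("greater", "less"):
                mine = wilcoxon_signed_rank_paired(x, y, d)
                ref = sps.wilcoxon(x, y, alternative=d, method="exact")
                assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_matches_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(0.2, 1.0, 40)
            y = rng.normal(0.0, 1.0, 40)
            for d in ("greater", "less"):
                mine = wilcoxon_signed_rank_paired(x, y, d)
                ref = sps.wilcoxon(x, y, alternative=d, method="approx", correction=True)
                assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearmanFdr:
    def _table(self):
        rng = np.random.default_rng(4)
        n = 12
        chl = rng.uniform(0.01, 1.0, n)
        return pd.DataFrame(
            {
                "chl": chl,
                "mono": np.log(chl) * -0.1 + 0.5,  # perfectly monotone in chl
                "noise": rng.normal(size=n),
                "flat": np.ones(n),
            }
        )

    def test_monotone_pair(self):
        out = spearman_fdr(self._table(), [("chl", "mono")])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_variable_undefined(self):
        out = spearman_fdr(self._table(), [("chl", "flat"), ("chl", "mono")])
        assert math.isnan(out["rho"].iloc[0])
        assert math.isnan(out["q"].iloc[0])
        assert not math.isnan(out["q"].iloc[1])

    def test_too_few_observations(self):
        t = self._table().head(3)
        with pytest.raises(ValueError, match="complete observations"):
            spearman_fdr(t, [("chl", "mono")])

    def test_bh_properties(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p
        assert (q >= p - 1e-12).all()
        assert ((0 <= q) & (q <= 1)).all()

    def test_bh_matches_hand_computation(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)


class TestTuningTrend:
    def test_exact_recovery_from_generating_equation(self):
        chl = np.array([0.01, 0.05, 0.1, 0.2])
        blue = -0.055 * np.log(chl) + 0.55
        m = fit_tuning_trend(chl, blue)
        assert m.fitted
        assert m.slope == pytest.approx(-0.055, abs=1e-9)
        assert m.intercept == pytest.approx(0.55, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_high_chl_stratum_reported_not_modeled(self):
        chl = np.array([0.01, 0.05, 0.1, 0.5, 1.0])
        blue = np.array([0.8, 0.7, 0.65, 0.3, 0.32])
        m = fit_tuning_trend(chl, blue)
        assert m.n_points == 3
        assert m.n_high == 2
        assert m.high_chl_mean == pytest.approx(0.31)

    def test_all_above_threshold_flagged(self):
        m = fit_tuning_trend([0.5, 1.0, 2.0], [0.3, 0.3, 0.3])
        assert not m.fitted
        assert math.isnan(m.slope)

    def test_slope_recovery_under_noise(self):
        rng = np.random.default_rng(6)
        chl = np.array([0.01, 0.02, 0.05, 0.1, 0.2])
        slopes = []
        for _ in range(100):
            blue = -0.055 * np.log(chl) + 0.55 + rng.normal(0, 0.02, chl.size)
            slopes.append(fit_tuning_trend(chl, blue).slope)
        assert np.mean(slopes) == pytest.approx(-0.055, abs=0.01)

    def test_arbitrary_generating_parameters_recovered(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.uniform(-0.2, 0.2)
            b = rng.uniform(0, 1)
            chl = rng.uniform(0.005, 0.24, 6)
            blue = a * np.log(chl) + b
            m = fit_tuning_trend(chl, blue)
            assert m.slope == pytest.approx(a, abs=1e-9)
            assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_positive_chl_required(self):
        with pytest.raises(ValueError):
            fit_tuning_trend([0.0, 0.1, 0.2], [0.5, 0.5, 0.5])
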