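"""Agreement statistics: ICC(A,1), Bland-Altman, Bartlett."""

import numpy as np
import pytest

import lithoseg as ls
from lithoseg.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    UndefinedICCError,
)


def _bartlett_oracle(groups):
    """Direct evaluation of the classical Bartlett formula."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    N = n.sum()
    sp2 = ((n - 1) * s2).sum() / (N - k)
    T = (N - k) * np.log(sp2) - ((n - 1) * np.log(s2)).sum()
    C = 1 + (np.sum(1 / (n - 1)) - 1 / (N - k)) / (3 * (k - 1))
    return T / C


def _icc_a1_oracle(x, y):
    """Independent ANOVA-style ICC(A,1) via explicit sums of squares."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    mean_r = data.mean(axis=1, keepdims=True)
    mean_c = data.mean(axis=0, keepdims=True)
    grand = data.mean()
    msr = k * np.sum((mean_r - grand) ** 2) / (n - 1)
    msc = n * np.sum((mean_c - grand) ** 2) / (k - 1)
    mse = np.sum((data - mean_r - mean_c + grand) ** 2) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_vectors_give_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ls.icc(x, x) == pytest.approx(1.0)

    def test_constant_bias_penalized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ls.icc(x, x + 1.0) < 1.0

    def test_matches_anova_oracle_to_1e10(self, rng):
        for _ in range(20):
            x = rng.normal(10, 3, size=20)
            y = x + rng.normal(0, 1, size=20)
            assert ls.icc(x, y) == pytest.approx(_icc_a1_oracle(x, y), abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(5, 2, size=25)
        y = x + rng.normal(0.3, 0.8, size=25)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(25), 2),
                "raters": np.repeat(["est", "ref"], 25),
                "scores": np.concatenate([x, y]),
            }
        )
        res = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        icc_a1 = float(res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert ls.icc(x, y) == pytest.approx(icc_a1, abs=1e-10)

    def test_symmetric_and_affine_invariant(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(0, 0.5, size=15)
        assert ls.icc(x, y) == pytest.approx(ls.icc(y, x), abs=1e-12)
        assert ls.icc(3 * x + 2, 3 * y + 2) == pytest.approx(ls.icc(x, y), abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedICCError):
            ls.icc(np.ones(5), np.ones(5))

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            ls.icc([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        report, points = ls.bland_altman(x, x)
        assert report.mean_diff == 0.0
        assert report.std_diff == 0.0
        assert report.loa_low == report.loa_high == 0.0
        np.testing.assert_allclose(points[:, 0], x)

    def test_plus_minus_one_hand_arithmetic(self):
        est = np.array([0.0, 0.0])
        ref = np.array([-1.0, 1.0])
        report, _ = ls.bland_altman(est, ref)
        assert report.mean_diff == 0.0
        assert report.std_diff == pytest.approx(np.sqrt(2))
        assert report.loa_high == pytest.approx(1.96 * np.sqrt(2))
        assert report.loa_low == pytest.approx(-1.96 * np.sqrt(2))

    def test_sign_convention_reference_minus_estimate(self):
        est = np.array([1.0, 2.0, 3.0])
        report, _ = ls.bland_altman(est, est + 0.5)
        assert report.mean_diff == pytest.approx(0.5)

    def test_matches_independent_columnwise_computation(self, rng):
        est = rng.normal(10, 2, size=30)
        ref = est + rng.normal(0.1, 0.4, size=30)
        report, _ = ls.bland_altman(est, ref)
        diffs = ref - est
        assert report.mean_diff == pytest.approx(diffs.mean())
        assert report.std_diff == pytest.approx(diffs.std(ddof=1))
        assert report.loa_low == pytest.approx(diffs.mean() - 1.96 * diffs.std(ddof=1))

    def test_single_pair_raises(self):
        with pytest.raises(InsufficientDataError):
            ls.bland_altman([1.0], [2.0])


class TestBartlett:
    def test_identical_groups_statistic_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = ls.bartlett_test(g, g.copy(), g.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 2

    def test_matches_direct_formula_to_1e8(self, rng):
        # fixed 3-group example
        g1 = np.array([8.88, 9.12, 9.04, 8.98, 9.00, 9.08, 9.01, 8.85, 9.06, 8.99])
        g2 = np.array([8.88, 8.95, 9.29, 9.44, 9.15, 9.58, 8.36, 9.18, 8.67, 9.05])
        g3 = np.array([8.95, 9.12, 8.95, 8.85, 9.03, 8.84, 9.07, 8.98, 8.86, 8.98])
        res = ls.bartlett_test(g1, g2, g3)
        assert res.statistic == pytest.approx(_bartlett_oracle([g1, g2, g3]), abs=1e-8)
        for _ in range(10):
            groups = [rng.normal(0, rng.uniform(0.5, 2), size=rng.integers(5, 30)) for _ in range(4)]
            res = ls.bartlett_test(*groups)
            assert res.statistic == pytest.approx(_bartlett_oracle(groups), abs=1e-8)

    def test_location_free(self, rng):
        groups = [rng.normal(0, 1, size=15) for _ in range(3)]
        shifted = [g + c for g, c in zip(groups, (5.0, -3.0, 100.0))]
        a = ls.bartlett_test(*groups)
        b = ls.bartlett_test(*shifted)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_scaling_one_group_shifts_log_variance(self, rng):
        groups = [rng.normal(0, 1, size=20) for _ in range(3)]
        base = [np.var(g, ddof=1) for g in groups]
        scaled = [groups[0] * 3.0] + groups[1:]
        s2 = [np.var(g, ddof=1) for g in scaled]
        assert np.log(s2[0]) - np.log(base[0]) == pytest.approx(2 * np.log(3.0), rel=1e-9)

    def test_zero_variance_group_raises(self):
        with pytest.raises(DegenerateVarianceError):
            ls.bartlett_test(np.ones(5), np.array([1.0, 2.0, 3.0]))

    def test_type_one_error_calibrated(self):
        # under the equal-variance null the rejection rate at alpha=0.05 must
        # sit inside the exact binomial 95% CI around 0.05 (1000 simulations)
        from scipy.stats import binom

        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1.0, size=101) for _ in range(4)]
            if ls.bartlett_test(*groups).p_value < 0.05:
                rejections += 1
        lo = binom.ppf(0.025, n_sim, 0.05)
        hi = binom.ppf(0.975, n_sim, 0.05)
        assert lo <= rejections <= hi


class TestEvaluateAllMethods:
    @staticmethod
    def _fake(ids, vols, diams, rng, sd_v=0.01, sd_d=0.1):
        return [
            ls.StoneMeasurement(i, v + rng.normal(0, sd_v), d + rng.normal(0, sd_d), 10, 5)
            for i, v, d in zip(ids, vols, diams)
        ]

    def _refs(self, ids, vols, diams):
        return [
            ls.RaterRecord(i, (v, v, v), (d, d, d), v, d) for i, v, d in zip(ids, vols, diams)
        ]

    def test_identical_methods_bartlett_p_one(self, rng):
        ids = [f"s{i}" for i in range(20)]
        vols = rng.uniform(0.1, 3.0, 20)
        diams = rng.uniform(5, 25, 20)
        est = self._fake(ids, vols, diams, np.random.default_rng(1))
        by_method = {m: list(est) for m in ("a", "b", "c", "d")}
        reports, comps = ls.evaluate_all_methods(by_method, self._refs(ids, vols, diams))
        assert len(reports) == 8
        assert comps["volume"].p_value == pytest.approx(1.0)
        assert comps["diameter"].p_value == pytest.approx(1.0)

    def test_shapes_and_doubled_error_detected(self, rng):
        ids = [f"s{i}" for i in range(101)]
        vols = rng.uniform(0.1, 5.0, 101)
        diams = rng.uniform(5, 30, 101)
        refs = self._refs(ids, vols, diams)
        by_method = {
            "m1": self._fake(ids, vols, diams, np.random.default_rng(11)),
            "m2": self._fake(ids, vols, diams, np.random.default_rng(12)),
            "m3": self._fake(ids, vols, diams, np.random.default_rng(13)),
            "bad": self._fake(ids, vols, diams, np.random.default_rng(14), sd_v=0.02, sd_d=0.2),
        }
        reports, comps = ls.evaluate_all_methods(by_method, refs)
        assert set(q for _, q in reports) == {"volume", "diameter"}
        assert comps["volume"].k == 4 and comps["volume"].dof == 3
        # doubled error SD must be detected at n=101
        assert comps["volume"].p_value < 0.05
        assert comps["diameter"].p_value < 0.05
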