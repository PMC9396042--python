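"""Cohort statistics: Welch test, thresholds, ECDF/coverage, LOESS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from radsens import (
    RadsensError,
    Regimen,
    RadioProfile,
    alpha_from_rsi,
    compute_gard,
    coverage_at_dose,
    gard_high_threshold,
    loess_smooth,
    optimal_dose_ecdf,
    summarize_group,
    welch_test,
)


def textbook_welch(a, b):
    """Independent textbook-formula oracle for the Welch test."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def profile_for_rsi(rsi, sid="S", regimen=Regimen(36, 2.0)):
    alpha = alpha_from_rsi(rsi)
    return RadioProfile(
        sample_id=sid,
        rsi=rsi,
        alpha=alpha,
        gard=compute_gard(alpha, regimen),
        regimen=regimen,
        hypofractionation_ok=rsi > 0.4,
    )


class TestSummarizeGroup:
    def test_constant_group(self):
        s = summarize_group([1, 1, 1], "tumor", "rsi")
        assert (s.mean, s.sd, s.n_samples) == (1.0, 0.0, 3)

    def test_sd_uses_n_minus_one(self):
        s = summarize_group([0, 2], "normal", "gard")
        assert s.mean == 1.0
        assert s.sd == pytest.approx(math.sqrt(2), abs=1e-5)

    def test_empty_group_rejected(self):
        with pytest.raises(RadsensError):
            summarize_group([], "tumor", "rsi")


class TestWelch:
    def test_identical_groups_give_zero_t_unit_p(self):
        res = welch_test([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-15)
        assert res.p_value == pytest.approx(1.0, abs=1e-15)

    def test_matches_textbook_oracle(self):
        # frozen from the pure-python formula: t=-1.0954451150, df=6, p=0.3153335962
        res = welch_test([1, 2, 3, 4], [2, 3, 4, 5])
        t, df, p = textbook_welch([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451150103321, abs=1e-12)
        assert df == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(0.3153335962012299, abs=1e-12)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.degrees_of_freedom == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_large_separation_small_p(self):
        res = welch_test([0, 0, 0.01], [10, 10.1, 9.9])
        assert res.p_value < 1e-4

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
    )
    @settings(max_examples=30, deadline=None)
    def test_group_swap_symmetry(self, a, b):
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            return
        r1 = welch_test(a, b)
        r2 = welch_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(RadsensError):
            welch_test([1], [1, 2])
        with pytest.raises(RadsensError):
            welch_test([1, 1], [2, 2])


class TestThreshold:
    @pytest.mark.parametrize(
        "values, expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5)]
    )
    def test_median_modes(self, values, expected):
        assert gard_high_threshold(values) == expected

    def test_fixed_mode(self):
        assert gard_high_threshold([1, 2], mode="fixed", fixed_value=21.0) == 21.0

    def test_fixed_without_value_rejected(self):
        with pytest.raises(RadsensError):
            gard_high_threshold([1, 2], mode="fixed")


class TestEcdfCoverage:
    def test_single_patient_single_step(self):
        profiles = [profile_for_rsi(0.45, "P1")]
        x, y, excluded = optimal_dose_ecdf(profiles, threshold=21.0)
        assert len(x) == 1 and y[0] == 1.0 and excluded == []

    def test_tied_patients_merge(self):
        profiles = [profile_for_rsi(0.45, "P1"), profile_for_rsi(0.45, "P2")]
        x, y, _ = optimal_dose_ecdf(profiles, 21.0)
        assert len(x) == 1 and y[0] == 1.0

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        rsis = rng.uniform(0.35, 0.55, size=14)
        profiles = [profile_for_rsi(r, f"P{i}") for i, r in enumerate(rsis)]
        x, y, _ = optimal_dose_ecdf(profiles, 21.0)
        doses = sorted(21.0 / (alpha_from_rsi(r) + 0.1) for r in rsis)
        for dose, frac in zip(x, y):
            assert frac == pytest.approx(
                sum(d <= dose + 1e-12 for d in doses) / 14, abs=1e-12
            )
        assert y[0] > 0 and y[-1] == 1.0
        assert np.all(np.diff(y) > 0)

    def test_unattainable_patient_excluded_and_reported(self):
        bad = RadioProfile(
            sample_id="PX",
            rsi=0.95,
            alpha=-0.12,  # alpha + beta*d < 0
            gard=0.0,
            regimen=Regimen(36, 2.0),
            hypofractionation_ok=True,
        )
        profiles = [profile_for_rsi(0.45, "P1"), bad]
        x, y, excluded = optimal_dose_ecdf(profiles, 21.0)
        assert excluded == ["PX"] and y[-1] == 1.0

    def test_coverage_equals_ecdf_pointwise(self):
        rng = np.random.default_rng(8)
        profiles = [
            profile_for_rsi(r, f"P{i}")
            for i, r in enumerate(rng.uniform(0.35, 0.55, size=14))
        ]
        x, y, _ = optimal_dose_ecdf(profiles, 21.0)
        for dose, frac in zip(x, y):
            assert coverage_at_dose(profiles, 21.0, dose) == pytest.approx(frac)
        # and off the step points
        assert coverage_at_dose(profiles, 21.0, 0.0) == 0.0
        assert coverage_at_dose(profiles, 21.0, x[-1] + 1) == 1.0

    def test_engineered_five_of_fourteen_at_seventy_gray(self):
        # choose RSIs so exactly 5 patients need <= 70 Gy for GARD 21:
        # dose = 21/(alpha+0.1) <= 70  <=>  alpha >= 0.2  <=>  rsi <= exp(-0.6)
        lo, hi = 0.45, 0.65  # exp(-0.6) ~ 0.5488
        rsis = [lo] * 5 + [hi] * 9
        profiles = [profile_for_rsi(r, f"P{i}") for i, r in enumerate(rsis)]
        cov = coverage_at_dose(profiles, 21.0, 70.0)
        assert cov == pytest.approx(5 / 14, abs=1e-12)
        assert round(cov, 3) == 0.357


class TestLoess:
    def oracle_fit(self, x, y, span, xq):
        """Per-point weighted polyfit oracle (numpy.polyfit code path)."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        k = max(int(np.ceil(span * len(x))), 2)
        out = []
        for x0 in xq:
            d = np.abs(x - x0)
            idx = np.argsort(d, kind="stable")[:k]
            h = d[idx].max()
            w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
            coeffs = np.polyfit(x[idx], y[idx], 1, w=np.sqrt(w))
            out.append(np.polyval(coeffs, x0))
        return np.clip(out, 0, 1)

    def test_reproduces_straight_line(self):
        x = np.linspace(0, 10, 20)
        y = 0.05 * x + 0.1
        _, fit = loess_smooth(x, y, span=0.5)
        assert np.allclose(fit, y, atol=1e-6)

    def test_constant_input_constant_output(self):
        x = np.linspace(0, 10, 10)
        _, fit = loess_smooth(x, np.full(10, 0.4))
        assert np.allclose(fit, 0.4, atol=1e-12)

    def test_logistic_toy_matches_wls_oracle(self):
        x = np.linspace(40, 90, 25)
        y = 1 / (1 + np.exp(-(x - 65) / 5))
        _, fit = loess_smooth(x, y, span=0.6)
        assert np.allclose(fit, self.oracle_fit(x, y, 0.6, x), atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(RadsensError):
            loess_smooth([1, 2, 3], [0, 0.5, 1])
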