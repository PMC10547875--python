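"""Tests for per-subject behavioral statistics and the exclusion cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chronobayes import (
    apply_exclusions,
    bootstrap_ip_ci,
    central_tendency_fit,
    iqr_filter,
    psychometric_fit,
    summarize_context,
    weber_fit,
)
from chronobayes.observer import TS_VALUES

TS = np.asarray(TS_VALUES)


class TestIqrFilter:
    def test_gross_outlier_flagged(self):
        mask = iqr_filter([0.50, 0.52, 0.55, 0.53, 5.0])
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_constant_list_flags_nothing(self):
        assert not iqr_filter([0.7] * 10).any()

    def test_matches_quantile_fence_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(10_000)
        # independent fence computation with interpolated quartiles
        q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
        expected = (v < q1 - 1.5 * (q3 - q1)) | (v > q3 + 1.5 * (q3 - q1))
        np.testing.assert_array_equal(iqr_filter(v), expected)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1.0, 2.0, 3.0])


class TestCentralTendencyFit:
    def test_exact_line_recovers_c_and_ip(self):
        means = 0.69 * TS + 0.285
        fit = central_tendency_fit(np.column_stack([TS, means]))
        assert fit.slope == pytest.approx(0.69, abs=1e-12)
        assert fit.C == pytest.approx(0.31, abs=1e-12)
        assert fit.IP == pytest.approx(0.285 / 0.31, rel=1e-12)

    def test_identity_line_has_undefined_ip(self):
        fit = central_tendency_fit(np.column_stack([TS, TS]))
        assert fit.C == pytest.approx(0.0, abs=1e-12)
        assert not fit.ip_defined

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        y = 0.6 * TS + 0.3 + rng.normal(0, 0.05, 5)
        fit = central_tendency_fit(np.column_stack([TS, y]))
        # closed-form OLS oracle
        sxx = np.sum((TS - TS.mean()) ** 2)
        slope = np.sum((TS - TS.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * TS.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_wrong_design_rejected(self):
        with pytest.raises(ValueError):
            central_tendency_fit([(0.4, 0.5), (0.6, 0.7)])


class TestWeberFit:
    def test_exact_line_recovers_parameters(self):
        # generating line uses group-level scalar-variability magnitudes
        var = 0.023 * TS**2 + 0.010
        fit = weber_fit(np.column_stack([TS**2, var]))
        assert fit.web_s == pytest.approx(0.023, abs=1e-12)
        assert fit.web_i == pytest.approx(0.010, abs=1e-12)

    def test_constant_variance(self):
        fit = weber_fit(np.column_stack([TS**2, np.full(5, 0.02)]))
        assert fit.web_s == pytest.approx(0.0, abs=1e-12)
        assert fit.web_i == pytest.approx(0.02, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        x = TS**2
        y = 0.03 * x + 0.01 + rng.normal(0, 0.005, 5)
        fit = weber_fit(np.column_stack([x, y]))
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.web_s == pytest.approx(slope, abs=1e-12)
        assert fit.web_i == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)
        assert fit.negative_slope == (slope < 0)


def _psych_points(mu, sigma, t_s1=1.1):
    ratios = np.array([0.52, 0.76, 0.88, 0.94, 1.06, 1.12, 1.24, 1.48])
    x = t_s1 * ratios
    return x, sps.norm.cdf((x - mu) / sigma)


class TestPsychometricFit:
    def test_noiseless_inversion(self):
        x, y = _psych_points(1.1, 0.2)
        fit = psychometric_fit(np.column_stack([x, y]), t_s1=1.1)
        assert fit.mu == pytest.approx(1.1, abs=1e-6)
        assert fit.sigma == pytest.approx(0.2, abs=1e-6)
        assert fit.R == 1.0
        assert not fit.excluded

    def test_flat_data_is_excluded(self):
        x, _ = _psych_points(1.1, 0.2)
        fit = psychometric_fit(np.column_stack([x, np.full(8, 0.5)]), t_s1=1.1)
        assert fit.excluded
        assert fit.R <= 0.50

    def test_binomial_recovery_within_bootstrap_error(self):
        # parametric bootstrap: recovered mu should sit within 3 SEs of truth
        mu, sigma, n = 1.1, 0.2, 200
        x, p = _psych_points(mu, sigma)
        rng = np.random.default_rng(8)
        mus = []
        for _ in range(200):
            y = rng.binomial(n, p) / n
            mus.append(psychometric_fit(np.column_stack([x, y]), t_s1=1.1).mu)
        mus = np.asarray(mus)
        se = mus.std(ddof=1)
        assert abs(mus[0] - mu) < 3 * se
        # and the bootstrap distribution itself is centred on the truth
        assert abs(mus.mean() - mu) < 3 * se / np.sqrt(200) + 0.01

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            psychometric_fit([(0.5, -0.1), (0.7, 0.5)])


class TestBootstrapIpCi:
    def _cohort(self, n, rng, slope=0.7, intercept=0.3, noise=0.05):
        means = intercept + slope * TS
        return means[None, :] + rng.normal(0, noise, size=(n, 5))

    def test_identical_subjects_give_zero_width(self):
        m = np.tile(0.7 * TS + 0.3, (6, 1))
        ci = bootstrap_ip_ci(m, B=500, seed=0)
        assert ci.lo == pytest.approx(ci.hi, abs=1e-12)
        assert ci.lo == pytest.approx(0.3 / 0.3, rel=1e-9)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(11)
        m = self._cohort(12, rng)
        a = bootstrap_ip_ci(m, B=2000, seed=5)
        b = bootstrap_ip_ci(m, B=2000, seed=5)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ip_ci(np.ones((3, 5)), B=10, seed=0)


def _ip_row(sid, task, eff, ip):
    return {"subject_id": sid, "task": task, "effector": eff, "IP": ip}


class TestApplyExclusions:
    def _tables(self):
        # engineered cohort: S1 clean; S2 has 3 bad psychometric conditions;
        # S3 has IP out of range in reproduction; S4 has 2 bad conditions (kept)
        psych = []
        for sid, n_bad in [("S1", 0), ("S2", 3), ("S3", 0), ("S4", 2)]:
            for i, ts1 in enumerate(TS_VALUES):
                for eff in ("hand", "eye"):
                    bad = (eff == "hand") and (i < n_bad)
                    psych.append(
                        {
                            "subject_id": sid,
                            "effector": eff,
                            "t_s1": ts1,
                            "R": 0.4 if bad else 0.9,
                        }
                    )
        ips = []
        for sid in ["S1", "S2", "S3", "S4"]:
            for task in ("reproduction", "discrimination"):
                for eff in ("hand", "eye"):
                    ip = 0.9
                    if sid == "S3" and task == "reproduction" and eff == "hand":
                        ip = 2.1
                    ips.append(_ip_row(sid, task, eff, ip))
        return pd.DataFrame(psych), pd.DataFrame(ips)

    def test_engineered_counts_match_exactly(self):
        psych, ips = self._tables()
        kept, report = apply_exclusions(psych, ips)
        assert report.n_conditions_excluded == 5  # 3 from S2 + 2 from S4
        assert report.n_subjects_excluded_psychometric == 1  # S2 (>2 rule)
        assert report.n_subjects_excluded_ip == 1  # S3 (range rule)
        assert set(kept) == {"S1", "S4"}

    def test_cascade_is_idempotent(self):
        psych, ips = self._tables()
        kept, _ = apply_exclusions(psych, ips)
        psych2 = psych[psych["subject_id"].isin(kept)]
        ips2 = ips[ips["subject_id"].isin(kept)]
        kept2, report2 = apply_exclusions(psych2, ips2)
        assert kept2 == kept
        assert not report2.excluded_subjects

    def test_undefined_ip_excludes_subject(self):
        psych, ips = self._tables()
        ips.loc[(ips["subject_id"] == "S1").idxmax(), "IP"] = np.nan
        kept, _ = apply_exclusions(psych, ips)
        assert "S1" not in kept


class TestSummarizeContext:
    def test_noise_free_reproduction_has_zero_bias_and_variance_terms(self):
        rows = []
        for ts in TS_VALUES:
            for _ in range(8):
                rows.append({"t_s": ts, "t_r": ts})
        s = summarize_context("S1", "reproduction", "hand", repro_trials=pd.DataFrame(rows))
        assert s.C == pytest.approx(0.0, abs=1e-12)
        assert s.web_s == pytest.approx(0.0, abs=1e-12)
        assert s.web_i == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(s.w_m)  # no fit attached

    def test_missing_condition_rejected(self):
        rows = [{"t_s": 0.4, "t_r": 0.5}] * 10 + [{"t_s": 0.7, "t_r": 0.8}] * 10
        with pytest.raises(ValueError):
            summarize_context("S1", "reproduction", "hand", repro_trials=pd.DataFrame(rows))
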