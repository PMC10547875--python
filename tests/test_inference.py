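"""Tests for group-level inference: RM-ANOVA, Tukey HSD, correlations, Bayes factors."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from chronobayes import (
    bonferroni,
    build_correlation_matrix,
    jzs_corr_bf10,
    pearson_with_bf,
    rm_anova_2x2,
    tukey_hsd,
)


def anova_oracle(y):
    """Independent sums-of-squares decomposition, written out longhand.

    Textbook two-way fully-within design: each effect tested against its own
    subject-by-effect interaction.  Returns {effect: (F, partial eta^2)}.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 2, 2)
    n = y.shape[0]
    grand = y.mean()
    ss = {}
    # effect sums of squares from marginal means
    ss["A"] = sum(2 * n * (y[:, a, :].mean() - grand) ** 2 for a in range(2))
    ss["B"] = sum(2 * n * (y[:, :, b].mean() - grand) ** 2 for b in range(2))
    ss["AB"] = sum(
        n * (y[:, a, b].mean() - y[:, a, :].mean() - y[:, :, b].mean() + grand) ** 2
        for a in range(2)
        for b in range(2)
    )
    ss["AS"] = sum(
        2 * (y[s, a, :].mean() - y[:, a, :].mean() - y[s].mean() + grand) ** 2
        for s in range(n)
        for a in range(2)
    )
    ss["BS"] = sum(
        2 * (y[s, :, b].mean() - y[:, :, b].mean() - y[s].mean() + grand) ** 2
        for s in range(n)
        for b in range(2)
    )
    ss["S"] = sum(4 * (y[s].mean() - grand) ** 2 for s in range(n))
    ss["total"] = ((y - grand) ** 2).sum()
    ss["ABS"] = ss["total"] - ss["S"] - ss["A"] - ss["B"] - ss["AB"] - ss["AS"] - ss["BS"]
    out = {}
    for eff, err in (("A", "AS"), ("B", "BS"), ("AB", "ABS")):
        f = (ss[eff] / 1.0) / (ss[err] / (n - 1))
        out[eff] = (f, ss[eff] / (ss[eff] + ss[err]))
    return out


class TestRmAnova:
    TOY = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 3.0, 5.0, 6.0],
            [1.0, 1.0, 2.0, 2.0],
            [4.0, 5.0, 6.0, 9.0],
        ]
    )

    def test_identical_cells_give_zero_f(self):
        y = np.tile(np.array([[2.0, 2.0], [2.0, 2.0]]), (5, 1, 1))
        y += np.arange(5)[:, None, None]  # subject offsets only
        for eff in rm_anova_2x2(y):
            assert eff.F == pytest.approx(0.0, abs=1e-20)

    def test_toy_table_matches_longhand_decomposition(self):
        expected = anova_oracle(self.TOY)
        got = rm_anova_2x2(self.TOY)
        for eff, key in zip(got, ("A", "B", "AB")):
            assert eff.F == pytest.approx(expected[key][0], abs=1e-10)
            assert eff.partial_eta_sq == pytest.approx(expected[key][1], abs=1e-10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            y = rng.normal(size=(8, 2, 2))
            expected = anova_oracle(y)
            for eff, key in zip(rm_anova_2x2(y), ("A", "B", "AB")):
                assert eff.F == pytest.approx(expected[key][0], abs=1e-10)

    def test_matches_pingouin_two_way_rm(self):
        rng = np.random.default_rng(23)
        y = rng.normal(size=(10, 2, 2)) + rng.normal(size=(10, 1, 1))
        rows = []
        for s in range(10):
            for a in range(2):
                for b in range(2):
                    rows.append({"subject": s, "A": f"a{a}", "B": f"b{b}", "y": y[s, a, b]})
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subject", detailed=True
        )
        ours = rm_anova_2x2(y, factor_names=("A", "B"))
        for eff, name in zip(ours, ("A", "B", "A * B")):
            pg_row = table[table["Source"] == name].iloc[0]
            assert eff.F == pytest.approx(pg_row["F"], rel=1e-8)
            assert eff.p == pytest.approx(pg_row["p_unc"], rel=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-50, 50))
    def test_location_invariance(self, shift):
        y = self.TOY + shift
        base = rm_anova_2x2(self.TOY)
        shifted = rm_anova_2x2(y)
        for a, b in zip(base, shifted):
            assert b.F == pytest.approx(a.F, rel=1e-6, abs=1e-9)
            assert b.partial_eta_sq == pytest.approx(a.partial_eta_sq, rel=1e-6, abs=1e-9)

    def test_missing_cell_rejected(self):
        y = self.TOY.copy()
        y[1, 2] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(y)


class TestTukeyHsd:
    def test_identical_cells_give_p_one(self):
        y = np.tile([1.0, 1.0, 1.0, 1.0], (6, 1))
        out = tukey_hsd(y)
        assert len(out) == 6
        assert (out["p_adj"] == 1.0).all()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(31)
        y = rng.normal(0, 1, size=(30, 4))
        pooled_sd = y.std()
        y[:, 2] += 10 * pooled_sd
        out = tukey_hsd(y)
        hits = out[(out["cell_1"] == "D_H") | (out["cell_2"] == "D_H")]
        assert (hits["p_adj"] < 0.01).all()

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(37)
        y = rng.normal(size=(12, 4))
        out = tukey_hsd(y)
        assert (out["p_adj"] >= out["p_unadj"] - 1e-12).all()


class TestJzsBayesFactor:
    def test_increasing_in_correlation_magnitude(self):
        bfs = [jzs_corr_bf10(r, 30) for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(bfs) > 0)

    def test_increasing_in_sample_size(self):
        bfs = [jzs_corr_bf10(0.4, n) for n in (10, 20, 40, 80)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("r", [-0.6, -0.2, 0.0, 0.1, 0.316, 0.527, 0.7, 0.9])
    @pytest.mark.parametrize("n", [10, 30, 60])
    def test_matches_pingouin_default(self, r, n):
        assert jzs_corr_bf10(r, n) == pytest.approx(pg.bayesfactor_pearson(r, n), rel=1e-6)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.5, 0.6])
    def test_jeffreys_closed_form_within_ten_percent(self, r):
        n = 30
        bf01_approx = np.sqrt((2 * n - 3) / np.pi) * (1 - r**2) ** ((n - 4) / 2)
        assert jzs_corr_bf10(r, n) == pytest.approx(1 / bf01_approx, rel=0.10)

    def test_perfect_correlation_is_unbounded(self):
        assert jzs_corr_bf10(1.0, 30) == np.inf


class TestPearsonWithBf:
    def test_identity_gives_r_one(self):
        x = np.linspace(0, 1, 12)
        r, p, bf, n = pearson_with_bf(x, x)
        assert r == 1.0
        assert bf == np.inf
        assert n == 12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_bf(np.ones(10), np.arange(10))

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([1.1, 2.2, 2.9, 4.3, 5.0, np.nan])
        *_, n = pearson_with_bf(x, y)
        assert n == 4


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.089, 4, 0.356), (0.929, 4, 1.0), (0.102, 2, 0.204), (0.3, 1, 0.3)]
    )
    def test_printed_pattern(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.integers(1, 12))
    def test_never_below_uncorrected_and_capped(self, p, m):
        out = bonferroni(p, m)
        assert p <= out <= 1.0


class TestBuildCorrelationMatrix:
    def _tables(self, rng, identical=False):
        subjects = [f"S{i}" for i in range(12)]
        rows_d, rows_m = [], []
        for ctx in ("R_H", "R_E", "D_H", "D_E"):
            for s in subjects:
                bias, sd = rng.uniform(0.1, 0.5), rng.uniform(0.1, 0.4)
                rows_d.append({"subject_id": s, "context": ctx, "bias": bias, "sd": sd})
                if identical:
                    rows_m.append({"subject_id": s, "context": ctx, "bias": bias, "sd": sd})
                else:
                    rows_m.append(
                        {
                            "subject_id": s,
                            "context": ctx,
                            "bias": rng.uniform(0.1, 0.5),
                            "sd": rng.uniform(0.1, 0.4),
                        }
                    )
        return pd.DataFrame(rows_d), pd.DataFrame(rows_m)

    def test_identical_tables_give_unit_correlations(self):
        d, m = self._tables(np.random.default_rng(5), identical=True)
        out = build_correlation_matrix(d, m)
        within = out[out["data_context"] == out["model_context"]]
        assert len(within) == 8
        np.testing.assert_allclose(within["r"].to_numpy(), 1.0, atol=1e-12)

    def test_has_24_rows_with_family_sizes(self):
        d, m = self._tables(np.random.default_rng(6))
        out = build_correlation_matrix(d, m)
        assert len(out) == 24
        assert (out.groupby("measure").size() == 12).all()
        assert (out["m"].value_counts()[4], out["m"].value_counts()[2]) == (16, 8)
        assert ((out["p_corr"] >= out["p_unc"]) & (out["p_corr"] <= 1.0)).all()

    def test_subject_mismatch_rejected(self):
        d, m = self._tables(np.random.default_rng(7))
        m = m[m["subject_id"] != "S3"]
        with pytest.raises(ValueError):
            build_correlation_matrix(d, m)

    def test_null_rejection_rate_near_five_percent(self):
        # at n = 30 the two-sided 5% critical value for |r| is ~0.361
        rng = np.random.default_rng(41)
        x = rng.standard_normal((10_000, 30))
        y = rng.standard_normal((10_000, 30))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        frac = np.mean(np.abs(r) > 0.361)
        assert frac == pytest.approx(0.05, abs=0.01)
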