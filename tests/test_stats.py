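"""Correlation, Fisher-Z, repeated-measures ANOVA and paired-t statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sympnet.stats import (
    StatsError,
    fisher_z_compare,
    paired_t_bonferroni,
    phase_correlation_suite,
    rm_anova_time,
    spearman_test,
)


class TestSpearmanTest:
    def test_perfect_inverse_rank(self):
        res = spearman_test(range(1, 9), range(8, 0, -1))
        assert res.rho == pytest.approx(-1.0)

    def test_monotone_pair_gives_unit_rho(self):
        x = [1, 3, 4, 10, 20]
        res = spearman_test(x, [v**3 for v in x])
        assert res.rho == pytest.approx(1.0)

    def test_exact_p_for_perfect_correlation_n8(self):
        res = spearman_test(range(8), range(8))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / math.factorial(8), rel=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        res = spearman_test(x, y)
        assert res.method == "exact"
        # independent oracle: enumerate every rank order of y directly
        rx = sps.rankdata(x)
        obs = abs(np.corrcoef(rx, sps.rankdata(y))[0, 1])
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(range(1, n + 1))
        )
        assert res.p_value == pytest.approx(count / math.factorial(n), rel=1e-12)

    def test_ties_force_asymptotic_and_match_scipy_rho(self):
        x = [1, 2, 2, 3, 5, 6, 7, 8]
        y = [2, 1, 4, 4, 5, 7, 6, 8]
        res = spearman_test(x, y)
        assert res.method == "asymptotic"
        assert res.rho == pytest.approx(sps.spearmanr(x, y)[0])

    def test_constant_vector_is_undefined(self):
        with pytest.raises(StatsError, match="constant"):
            spearman_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.5, 30, 0.5, 40)
        assert z == 0 and p == 1

    def test_antisymmetric_in_arguments(self):
        z1, p1 = fisher_z_compare(0.8, 25, 0.3, 25)
        z2, p2 = fisher_z_compare(0.3, 25, 0.8, 25)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_closed_form_value(self):
        z, p = fisher_z_compare(0.9, 50, 0.0, 50)
        expected = (math.atanh(0.9) - 0.0) / math.sqrt(2 / 47)
        assert z == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(2 * sps.norm.sf(abs(expected)), abs=1e-12)

    def test_degenerate_r(self):
        with pytest.raises(StatsError):
            fisher_z_compare(1.0, 20, 0.5, 20)


class TestRmAnova:
    def test_design_degrees_of_freedom(self, rng):
        X = rng.normal(size=(8, 3))
        _, df1, df2, _ = rm_anova_time(X)
        assert (df1, df2) == (2, 14)

    def test_equal_column_means_give_near_zero_f(self, rng):
        subj = rng.normal(size=(8, 1))
        X = np.repeat(subj, 3, axis=1) + rng.normal(scale=0.1, size=(8, 3))
        F, _, _, p = rm_anova_time(X)
        assert p > 0.2

    def test_matches_sums_of_squares_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        F, df1, df2, p = rm_anova_time(X)
        g, t = X.shape
        grand = X.mean()
        ss_time = g * ((X.mean(0) - grand) ** 2).sum()
        ss_err = (
            ((X - X.mean(0) - X.mean(1)[:, None] + grand) ** 2).sum()
        )
        F_oracle = (ss_time / (t - 1)) / (ss_err / ((t - 1) * (g - 1)))
        assert F == pytest.approx(F_oracle, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(F_oracle, df1, df2), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(8, 3))
        F, df1, df2, p = rm_anova_time(X)
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "subject": np.repeat(np.arange(8), 3),
                "time": np.tile(np.arange(3), 8),
            }
        )
        tbl = pg.rm_anova(data=long, dv="y", within="time", subject="subject")
        assert F == pytest.approx(float(tbl["F"].iloc[0]), rel=1e-8)
        assert p == pytest.approx(float(tbl["p_unc"].iloc[0]), rel=1e-8)

    def test_missing_cells_rejected(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(StatsError):
            rm_anova_time(X)


class TestPairedT:
    def test_identical_columns_policy(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        out = paired_t_bonferroni(X)
        assert (out["p_adj"] == 1.0).all()
        assert (out["t"] == 0.0).all()

    def test_constant_shift_direction_and_min_p(self, rng):
        a = rng.normal(size=12)
        X = np.column_stack([a, a + 2.0, a])
        out = paired_t_bonferroni(X, labels=["b", "c", "p"])
        row = out[(out["a"] == "b") & (out["b"] == "c")].iloc[0]
        # exact positive shift: limiting t is +inf, smallest attainable p
        assert row["t"] == math.inf and row["p_raw"] == 0.0

    def test_matches_t_distribution_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        out = paired_t_bonferroni(X)
        for _, row in out.iterrows():
            i = {"t0": 0, "t1": 1, "t2": 2}[row["a"]]
            j = {"t0": 0, "t1": 1, "t2": 2}[row["b"]]
            d = X[:, j] - X[:, i]
            t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
            p = 2 * sps.t.sf(abs(t), df=len(d) - 1)
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p_raw"] == pytest.approx(p, abs=1e-10)
            assert row["p_adj"] == pytest.approx(min(1.0, 3 * p), abs=1e-10)


class TestCorrelationSuite:
    def _series(self, strengths, deltas):
        n = len(strengths)
        return pd.DataFrame(
            {
                "group": [f"g{i}" for i in range(n)],
                "strength_baseline": strengths,
                "strength_change": np.asarray(strengths) + np.linspace(0.1, 1.0, n),
                "strength_postchange": np.asarray(strengths) + 0.5,
                "mean_delta": deltas,
                "severity_baseline": np.linspace(13, 20, n),
                "severity_change": np.linspace(12, 6, n),
                "severity_postchange": np.linspace(11, 4, n),
            }
        )

    def test_constructed_gradient_gives_perfect_negative(self):
        s = self._series(np.linspace(2.4, 1.0, 8), np.linspace(0.5, 20, 8))
        out = phase_correlation_suite(s)
        row = out[out["name"] == "baseline_strength_vs_max_change"].iloc[0]
        assert row["rho"] == pytest.approx(-1.0)

    def test_constant_strengths_reported_na_with_reason(self):
        s = self._series([1.5] * 8, np.linspace(0.5, 20, 8))
        out = phase_correlation_suite(s)
        row = out[out["name"] == "baseline_strength_vs_max_change"].iloc[0]
        assert np.isnan(row["rho"]) and "constant" in row["note"]

    def test_stratified_week12_rows_present_when_supplied(self):
        s = self._series(np.linspace(2.4, 1.0, 8), np.linspace(0.5, 20, 8))
        s["week12_delta"] = np.linspace(0.5, 16, 8)
        s["week12_delta_good"] = np.linspace(0.5, 18, 8)
        s["week12_delta_poor"] = np.linspace(0.5, 10, 8)
        out = phase_correlation_suite(s)
        w12 = out[out["name"] == "baseline_strength_vs_week12_change"]
        assert set(w12["stratum"]) == {"all", "good", "poor"}
        assert (w12["rho"] < 0).all()
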