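"""Second-level statistics: MC count null, trends, subnetworks, split-half."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chisquare, kstest

from imaging_greml import (SimConfig, classify_subnetworks,
                           expected_false_positives, fit_linear_trend,
                           fit_quadratic_trend, mc_count_pvalue,
                           percent_bsc, simulate_bold_session,
                           split_half_r2)
from imaging_greml.exceptions import ConfigError

# Published per-ROI degree statistics (mean, SD) for the ambiguous contrast;
# the bold / plain marks in the source table give the expected subnetworks.
TABLE1_DEGREE = {
    "L_MVLFC": (9.91, 4.65), "R_MVLFC": (10.20, 4.87),
    "L_MDLFC": (10.72, 4.87), "R_MDLFC": (11.43, 4.95),
    "L_PMC": (10.46, 5.07), "R_PMC": (11.83, 4.98),
    "R_PreSMA": (7.88, 5.06), "L_RhinalSulcus": (5.48, 3.92),
    "R_RhinalSulcus": (6.17, 4.23), "L_Amygdala": (7.36, 4.44),
    "R_Amygdala": (7.99, 4.78), "L_AntSTS": (8.02, 4.88),
    "R_AntSTS": (10.45, 5.19), "L_PostSTS": (12.70, 4.78),
    "R_PostSTS": (14.03, 4.44), "L_FFA": (11.60, 4.66),
    "R_FFA": (12.20, 4.54), "L_LOC": (12.29, 4.27), "R_LOC": (12.21, 4.23),
    "L_V2V3": (9.99, 4.65), "R_V2V3": (9.81, 4.64),
    "L_Cerebellum": (11.22, 4.74), "R_Cerebellum": (8.89, 4.67),
    "L_Putamen": (7.64, 4.81), "R_Putamen": (8.42, 4.99),
}


class TestExpectedFalsePositives:
    @pytest.mark.parametrize(
        "n,alpha,want", [(25, 0.05, 1.25), (50, 0.05, 2.5), (100, 0.0, 0.0)]
    )
    def test_closed_form(self, n, alpha, want):
        assert expected_false_positives(n, alpha) == want

    def test_invalid_alpha(self):
        with pytest.raises(ConfigError):
            expected_false_positives(25, 1.5)


class TestMcCountPvalue:
    def _random_corr(self, seed=0, k=25):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((k, 2 * k))
        C = np.corrcoef(A)
        return C

    def test_zero_observed_count_gives_p_one(self):
        dist = mc_count_pvalue(self._random_corr(1), 0,
                               n_realizations=2000, seed=1)
        assert dist.p_value == 1.0

    def test_identity_correlation_matches_binomial(self):
        """Independence limit: counts distributed Binomial(25, 0.05)."""
        dist = mc_count_pvalue(np.eye(25), 9, n_realizations=50_000, seed=2)
        k = np.arange(26)
        expected = binom.pmf(k, 25, 0.05) * dist.n_realizations
        # pool the sparse upper tail for a valid chi-square test
        cut = np.max(np.nonzero(expected >= 5)[0]) + 1
        obs = np.r_[dist.histogram[:cut], dist.histogram[cut:].sum()]
        exp = np.r_[expected[:cut], expected[cut:].sum()]
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01

    def test_identity_tail_matches_exact_binomial(self):
        """P(count >= 9) under independence: MC vs closed-form binomial."""
        dist = mc_count_pvalue(np.eye(25), 9, n_realizations=50_000, seed=3)
        exact = float(binom.sf(8, 25, 0.05))
        mc_se = np.sqrt(exact * (1 - exact) / dist.n_realizations)
        assert abs(dist.p_value - exact) < 4 * mc_se + 2 / dist.n_realizations

    def test_comonotone_limit_concentrates_on_extremes(self):
        ones = np.ones((25, 25))
        dist = mc_count_pvalue(ones, 5, n_realizations=5000, seed=4)
        mass = dist.histogram[0] + dist.histogram[25]
        assert mass == dist.n_realizations

    def test_monotone_in_observed_count(self):
        C = self._random_corr(5)
        ps = [
            mc_count_pvalue(C, k, n_realizations=5000, seed=6).p_value
            for k in range(0, 26, 5)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_boundary_mixture_method_calibrated(self):
        """Mixture-null per-ROI p-values are significant at rate alpha."""
        dist = mc_count_pvalue(np.eye(25), 2, alpha=0.05,
                               n_realizations=20_000, seed=7,
                               method="boundary-mixture")
        mean_count = np.average(np.arange(26), weights=dist.histogram)
        se = np.sqrt(25 * 0.05 * 0.95 / dist.n_realizations)
        assert abs(mean_count - 1.25) < 4 * se * 5

    def test_non_psd_repaired_with_warning(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.9
        C[1, 2] = C[2, 1] = 0.9
        C[0, 2] = C[2, 0] = -0.9  # violates PSD
        with pytest.warns(RuntimeWarning, match="PSD"):
            dist = mc_count_pvalue(C, 1, n_realizations=500, seed=8)
        assert 0 < dist.p_value <= 1

    def test_bad_observed_count_raises(self):
        with pytest.raises(ConfigError):
            mc_count_pvalue(np.eye(25), 26, n_realizations=100, seed=9)

    def test_reproducible_under_seed(self):
        C = self._random_corr(10)
        d1 = mc_count_pvalue(C, 4, n_realizations=2000, seed=11)
        d2 = mc_count_pvalue(C, 4, n_realizations=2000, seed=11)
        np.testing.assert_array_equal(d1.histogram, d2.histogram)
        assert d1.p_value == d2.p_value


class TestTrendFits:
    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        fit = fit_linear_trend(x, 2 * x)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.df1 == 1 and fit.df2 == 8

    def test_four_point_slope_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        fit = fit_linear_trend(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert fit.coefficients[1] == pytest.approx(sxy / sxx, rel=1e-12)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, rel=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(500):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            ps.append(fit_linear_trend(x, y).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_exact_parabola_r2_one(self):
        x = np.linspace(-2, 2, 12)
        fit = fit_quadratic_trend(x, 1.0 + 0.5 * x - 2.0 * x**2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_quadratic_df_for_25_rois(self):
        rng = np.random.default_rng(13)
        fit = fit_quadratic_trend(rng.standard_normal(25),
                                  rng.standard_normal(25))
        assert (fit.df1, fit.df2) == (2, 22)

    def test_inverted_u_detected(self):
        rng = np.random.default_rng(14)
        x = np.linspace(0, 10, 25)
        y = -0.4 * (x - 5.0) ** 2 + 8.0 + 0.3 * rng.standard_normal(25)
        fit = fit_quadratic_trend(x, y)
        assert fit.coefficients[2] < 0
        assert fit.p_value < 0.001


class TestClassifySubnetworks:
    def _published_stats(self):
        return pd.DataFrame(
            {
                "degree_mean": [v[0] for v in TABLE1_DEGREE.values()],
                "degree_sd": [v[1] for v in TABLE1_DEGREE.values()],
            },
            index=list(TABLE1_DEGREE),
        )

    def test_recovers_published_grouping(self):
        """The verbal rule, applied to the published degree table with
        recorded quantile parameters, selects the published 4+4 ROIs."""
        labels = classify_subnetworks(
            self._published_stats(), k=4, mean_band=(1 / 3, 0.70)
        )
        assert set(labels.rois("Optional")) == {
            "R_MVLFC", "L_MDLFC", "L_PMC", "R_AntSTS"
        }
        assert set(labels.rois("Obligatory")) == {
            "R_PostSTS", "R_FFA", "L_LOC", "R_LOC"
        }

    def test_constructed_structure_recovered_with_defaults(self):
        """High-SD/mid-mean vs high-mean/low-SD groups built by hand."""
        rng = np.random.default_rng(15)
        means = np.r_[np.full(4, 10.0), np.full(4, 14.0),
                      rng.uniform(8, 12, 17)]
        sds = np.r_[np.full(4, 6.0), np.full(4, 2.0),
                    rng.uniform(3.5, 5.0, 17)]
        stats = pd.DataFrame(
            {"degree_mean": means, "degree_sd": sds},
            index=[f"R{i}" for i in range(25)],
        )
        labels = classify_subnetworks(stats, k=4)
        assert labels.rois("Optional") == ["R0", "R1", "R2", "R3"]
        assert labels.rois("Obligatory") == ["R4", "R5", "R6", "R7"]

    def test_identical_stats_warn_all_neither(self):
        stats = pd.DataFrame({"degree_mean": [5.0] * 10,
                              "degree_sd": [2.0] * 10})
        with pytest.warns(RuntimeWarning):
            labels = classify_subnetworks(stats, k=2)
        assert (labels.labels == "Neither").all()

    def test_k_zero_all_neither(self):
        labels = classify_subnetworks(self._published_stats(), k=0)
        assert (labels.labels == "Neither").all()

    def test_infeasible_k_raises_with_feasible_bound(self):
        stats = self._published_stats()
        with pytest.raises(ConfigError, match="feasible k"):
            classify_subnetworks(stats, k=20)

    def test_parameters_recorded(self):
        labels = classify_subnetworks(self._published_stats(), k=4)
        assert labels.params["k"] == 4
        assert "mean_band" in labels.params


class TestSplitHalf:
    def test_identical_groups_r2_one(self):
        a = np.arange(25, dtype=float)
        assert split_half_r2(a, a.copy()) == pytest.approx(1.0)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(16)
        r2 = split_half_r2(rng.standard_normal(25), rng.standard_normal(25))
        assert r2 < 0.3

    def test_stable_roi_profile_reproducible_across_halves(self):
        """A cohort with a fixed regional activation profile gives
        R^2 > 0.9 between the per-ROI means of two random halves."""
        cfg = SimConfig(n_subjects=160, n_snps=5, n_causal=1, seed=17)
        rng = np.random.default_rng(17)
        adj = np.zeros((25, 25), dtype=bool)
        vals = np.array([
            percent_bsc(simulate_bold_session(cfg, adj, rng),
                        "ambiguous").to_numpy()
            for _ in range(cfg.n_subjects)
        ])
        half = cfg.n_subjects // 2
        r2 = split_half_r2(vals[:half].mean(axis=0),
                           vals[half:].mean(axis=0))
        assert r2 > 0.9

    def test_constant_profile_rejected(self):
        with pytest.raises(ConfigError):
            split_half_r2(np.ones(25), np.ones(25))
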