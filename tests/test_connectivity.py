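"""Condition series extraction, correlation graphs, %BSC and standardization."""

import numpy as np
import pandas as pd
import pytest

from imaging_greml import (RoiTimeSeries, SimConfig,
                           condition_correlation_matrix,
                           connection_proportions, degree_population_stats,
                           extract_condition_series, percent_bsc,
                           regress_nuisance, simulate_bold_session,
                           standardize_phenotypes, threshold_and_degree)
from imaging_greml.config import default_block_design
from imaging_greml.connectivity import ConnectivityGraph, connectivity_graph
from imaging_greml.exceptions import ConfigError, DesignError


def _toy_ts(n_roi=4, seed=0, design=None, signal=None):
    design = default_block_design() if design is None else design
    rng = np.random.default_rng(seed)
    n = design.size
    if signal is None:
        signal = 100.0 + rng.standard_normal((n, n_roi))
    frame = pd.DataFrame(signal, columns=[f"ROI{i}" for i in range(n_roi)])
    frame["WM"] = 100.0 + rng.standard_normal(n)
    frame["CSF"] = 100.0 + rng.standard_normal(n)
    return RoiTimeSeries(subject="toy", frame=frame, design=design)


class TestRegressNuisance:
    def test_no_leakage_preserves_signal(self):
        ts = _toy_ts(seed=1)
        out = regress_nuisance(ts)
        for c in ts.roi_names:
            r = np.corrcoef(ts.frame[c] - ts.frame[c].mean(),
                            out.frame[c])[0, 1]
            # OLS on two unrelated regressors absorbs ~2/160 of variance
            # by chance (more in unlucky channels), so r sits near but
            # not at 1
            assert r > 0.98

    def test_wm_copy_roi_removed(self):
        ts = _toy_ts(seed=2)
        ts.frame["ROI0"] = ts.frame["WM"]
        out = regress_nuisance(ts)
        assert out.frame["ROI0"].var() < 1e-20 * ts.frame["WM"].var()

    def test_injected_leakage_removed(self):
        ts = _toy_ts(seed=3)
        leak = 0.8
        contaminated = ts.frame.copy()
        contaminated["ROI1"] = (ts.frame["ROI1"]
                                + leak * (ts.frame["WM"] - 100.0))
        ts2 = RoiTimeSeries("toy", contaminated, ts.design)
        out = regress_nuisance(ts2)
        r = np.corrcoef(out.frame["ROI1"], ts2.frame["WM"])[0, 1]
        assert abs(r) < 0.02

    def test_constant_nuisance_warns_and_drops(self):
        ts = _toy_ts(seed=4)
        ts.frame["CSF"] = 7.0
        with pytest.warns(RuntimeWarning, match="CSF"):
            out = regress_nuisance(ts)
        assert out.n_volumes == ts.n_volumes


class TestExtractConditionSeries:
    def test_standard_lengths(self):
        ts = _toy_ts(seed=5)
        assert len(extract_condition_series(ts, "ambiguous")) == 40
        assert len(extract_condition_series(ts, "angry")) == 40
        assert len(extract_condition_series(ts, "control")) == 72

    def test_blockwise_mean_centering(self):
        ts = _toy_ts(seed=6)
        out = extract_condition_series(ts, "ambiguous").to_numpy()
        for b in range(5):
            block = out[b * 8:(b + 1) * 8]
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_signal_gives_zero(self):
        design = default_block_design()
        sig = np.full((160, 3), 42.0)
        ts = _toy_ts(n_roi=3, design=design, signal=sig)
        out = extract_condition_series(ts, "control").to_numpy()
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_unknown_condition_raises(self):
        with pytest.raises(ConfigError):
            extract_condition_series(_toy_ts(), "happy")

    def test_shift_off_end_is_error(self):
        design = np.array(
            ["rest"] * 144 + ["ambiguous"] * 8 + ["rest"] * 0 + ["control"] * 8,
            dtype=object,
        )
        ts = _toy_ts(design=design, seed=7)
        with pytest.raises(DesignError, match="runs past"):
            extract_condition_series(ts, "control")

    def test_short_block_is_error(self):
        design = default_block_design().copy()
        first_amb = int(np.flatnonzero(design == "ambiguous")[0])
        design[first_amb] = "rest"  # truncate first block to 7 volumes
        ts = _toy_ts(design=design, seed=8)
        with pytest.raises(DesignError, match="expected 8"):
            extract_condition_series(ts, "ambiguous")


class TestCorrelationAndDegree:
    def test_duplicated_and_flipped_channels(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(112)
        face = pd.DataFrame({
            "a": base[:40], "b": base[:40], "c": -base[:40],
        })
        ctrl = pd.DataFrame({
            "a": base[40:], "b": base[40:], "c": -base[40:],
        })
        corr = condition_correlation_matrix(face, ctrl)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_independent_noise_rarely_crosses_threshold(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.standard_normal((112, 25)))
        corr = condition_correlation_matrix(data, None)
        iu = np.triu_indices(25, 1)
        frac_below = (np.abs(corr.to_numpy()[iu]) < 0.3).mean()
        assert frac_below >= 0.95

    def test_exact_threshold_is_not_an_edge(self):
        corr = pd.DataFrame(np.eye(3), columns=list("abc"),
                            index=list("abc"))
        corr.loc["a", "b"] = corr.loc["b", "a"] = 0.3
        corr.loc["a", "c"] = corr.loc["c", "a"] = 0.30001
        adj, degree = threshold_and_degree(corr)
        assert not adj[0, 1]  # strict inequality at r = 0.3
        assert adj[0, 2]
        assert degree.tolist() == [1, 0, 1]

    def test_negative_correlations_never_edges(self):
        corr = pd.DataFrame(np.eye(2))
        corr.iloc[0, 1] = corr.iloc[1, 0] = -0.9
        adj, degree = threshold_and_degree(corr)
        assert degree.sum() == 0

    def test_degree_equals_brute_force_and_handshake(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = rng.integers(3, 26)
            M = rng.uniform(-1, 1, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            corr = pd.DataFrame(M)
            adj, degree = threshold_and_degree(corr)
            brute = [
                sum(1 for j in range(n) if j != i and M[i, j] > 0.3)
                for i in range(n)
            ]
            assert degree.tolist() == brute
            assert degree.sum() % 2 == 0  # handshake lemma


class TestPercentBsc:
    def test_equal_condition_and_control_gives_zero(self):
        sig = np.full((160, 3), 50.0)
        ts = _toy_ts(n_roi=3, signal=sig)
        np.testing.assert_allclose(percent_bsc(ts, "ambiguous"), 0.0,
                                   atol=1e-12)

    def test_linearity_in_contrast_amplitude(self):
        """Doubling the signal fluctuation about the run mean doubles %BSC."""
        rng = np.random.default_rng(12)
        sig = 100.0 + rng.standard_normal((160, 3))
        ts1 = _toy_ts(n_roi=3, signal=sig)
        run_mean = sig.mean(axis=0, keepdims=True)
        ts2 = _toy_ts(n_roi=3, signal=run_mean + 2 * (sig - run_mean))
        b1 = percent_bsc(ts1, "ambiguous").to_numpy()
        b2 = percent_bsc(ts2, "ambiguous").to_numpy()
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-9)

    def test_cohort_mean_recovers_ground_truth(self):
        cfg = SimConfig(n_subjects=150, n_snps=5, n_causal=1, seed=13)
        rng = np.random.default_rng(13)
        adj = np.zeros((25, 25), dtype=bool)
        vals = []
        for _ in range(cfg.n_subjects):
            ts = simulate_bold_session(cfg, adj, rng)
            vals.append(percent_bsc(ts, "ambiguous").to_numpy())
        est = np.mean(vals, axis=0)
        truth = ts.truth["bsc"]["ambiguous"]
        se = np.std(vals, axis=0, ddof=1) / np.sqrt(cfg.n_subjects)
        assert np.all(np.abs(est - truth) < 4 * se + 0.01)


class TestStandardize:
    def _table(self, n=600, seed=14, offsets=(0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        site = rng.integers(0, len(offsets), size=n)
        y = rng.standard_normal((n, 3)) + np.asarray(offsets)[site][:, None]
        tab = pd.DataFrame(y, columns=["r1", "r2", "r3"])
        tab.insert(0, "fid", [f"F{i}" for i in range(n)])
        tab.insert(1, "iid", [f"I{i}" for i in range(n)])
        tab.insert(2, "site", site)
        tab.insert(3, "sex", rng.integers(0, 2, size=n))
        return tab

    def test_single_site_is_plain_zscore(self):
        tab = self._table(offsets=(0.0,))
        out = standardize_phenotypes(tab)
        x = tab["r1"].to_numpy()
        want = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(out["r1"].to_numpy(), want, atol=1e-12)

    def test_per_site_mean_zero_sd_one(self):
        out = standardize_phenotypes(self._table(offsets=(0.0, 1.0, -2.0)))
        for _, sub in out.groupby("site"):
            np.testing.assert_allclose(sub[["r1", "r2", "r3"]].mean(), 0.0,
                                       atol=1e-12)
            np.testing.assert_allclose(sub[["r1", "r2", "r3"]].std(ddof=1),
                                       1.0, atol=1e-12)

    def test_site_offsets_removed(self):
        tab = self._table(offsets=(0.0, 3.0, -3.0))
        out = standardize_phenotypes(tab)
        site_means = out.groupby("site")["r1"].mean()
        assert site_means.abs().max() < 1e-12


class TestPopulationStats:
    def _graph(self, adj, names):
        adj = np.asarray(adj, dtype=bool)
        corr = pd.DataFrame(adj.astype(float), index=names, columns=names)
        deg = pd.Series(adj.sum(axis=1), index=names, name="degree")
        return ConnectivityGraph("ambiguous", corr, adj, deg)

    def test_identical_graphs_zero_sd(self):
        names = list("abcd")
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        graphs = [self._graph(adj, names)] * 5
        stats = degree_population_stats(graphs)
        assert (stats["degree_sd"] == 0).all()

    def test_two_subject_toy_hand_computed(self):
        names = list("abc")
        a1 = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=bool)
        a2 = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool)
        stats = degree_population_stats(
            [self._graph(a1, names), self._graph(a2, names)]
        )
        # degrees: a -> (2, 1), b -> (1, 1), c -> (1, 0)
        np.testing.assert_allclose(stats["degree_mean"], [1.5, 1.0, 0.5])
        np.testing.assert_allclose(stats["degree_sd"], [0.5, 0.0, 0.5])

    def test_output_dimensions_for_standard_network(self, small_config):
        rng = np.random.default_rng(15)
        graphs = []
        for _ in range(3):
            from imaging_greml import simulate_subject_graph

            adj = simulate_subject_graph(small_config, rng)
            ts = simulate_bold_session(small_config, adj, rng)
            graphs.append(connectivity_graph(ts, "ambiguous"))
        stats = degree_population_stats(graphs)
        assert stats.shape == (25, 2)

    def test_connection_proportions_properties(self):
        names = list("abc")
        a1 = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=bool)
        a2 = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool)
        prop = connection_proportions(
            [self._graph(a1, names), self._graph(a2, names)]
        )
        assert prop.loc["a", "b"] == 1.0  # edge in every subject
        assert prop.loc["a", "c"] == 0.5
        np.testing.assert_allclose(np.diag(prop), 1.0)
        np.testing.assert_allclose(prop.to_numpy(), prop.to_numpy().T)
        assert ((prop.to_numpy() >= 0) & (prop.to_numpy() <= 1)).all()
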