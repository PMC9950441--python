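import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confclust.massuni import (
    ClusterResult,
    ModelSpec,
    assign_tertiles,
    benjamini_hochberg,
    build_design,
    cluster_regression,
    effect_amplitude,
    extract_clusters,
    fit_lmm,
    reml_scan,
    scan_responsive_electrodes,
    significant_runs,
)


class TestBenjaminiHochberg:
    def test_all_ones_no_rejection(self):
        reject, q = benjamini_hochberg(np.ones(10))
        assert not reject.any()
        np.testing.assert_allclose(q, 1.0)

    def test_handworked_stepup(self):
        # thresholds 0.0125 / 0.025 / 0.0375 / 0.05: the largest p (0.04)
        # is below its threshold 0.05, so all four are rejected
        p = np.array([0.001, 0.02, 0.03, 0.04])
        reject, _ = benjamini_hochberg(p, alpha=0.05)
        assert reject.all()

    def test_single_p(self):
        reject, _ = benjamini_hochberg(np.array([0.04]), alpha=0.05)
        assert reject.all()

    def test_q_geq_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        _, q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500) ** 2
        reject, q = benjamini_hochberg(p, alpha=0.05)
        ref_reject, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, ref_reject)
        np.testing.assert_allclose(q, ref_q, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50),
           st.floats(min_value=0.01, max_value=0.2))
    def test_monotone_in_alpha(self, pvals, alpha):
        p = np.array(pvals)
        r1, _ = benjamini_hochberg(p, alpha=alpha)
        r2, _ = benjamini_hochberg(p, alpha=min(alpha * 2, 1.0))
        assert np.all(r2[r1])  # enlarging alpha never shrinks the rejection set

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def _lmm_frame(rng, n_part=8, n_per=30, beta=0.5, group_sd=1.0, resid_sd=1.0):
    rows = []
    for i in range(n_part):
        u = rng.normal(0, group_sd)
        x = rng.normal(size=n_per)
        grp = "ssd" if i % 2 else "control"
        y = 1.0 + beta * x + u + rng.normal(0, resid_sd, n_per)
        rows.append(pd.DataFrame({
            "participant": f"p{i}", "group": grp, "correct": (x > 0).astype(int),
            "amplitude": y, "x": x,
        }))
    return pd.concat(rows, ignore_index=True)


class TestFitLmm:
    def test_zero_group_variance_matches_ols(self):
        # identical data pattern in every participant: between-group variance
        # is zero, REML hits the boundary and GLS reduces to OLS
        x = np.tile(np.linspace(-1, 1, 20), 4)
        part = np.repeat([f"p{i}" for i in range(4)], 20)
        y = 2.0 + 0.7 * x + np.tile(np.sin(np.arange(20)), 4) * 0.3
        codes = pd.factorize(part)[0]
        X = np.column_stack([np.ones_like(x), x])
        fit = reml_scan(X, y[:, None], [codes], ["Intercept", "x"])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta[:, 0], beta_ols, atol=1e-6)
        assert fit.ratios[0, 0] == 0.0

    def test_balanced_anova_closed_form(self):
        # balanced one-way layout: REML variance components equal the
        # classical ANOVA estimators MSW and (MSB - MSW) / n
        rng = np.random.default_rng(2)
        G, n = 12, 25
        u = rng.normal(0, 1.2, G)
        y = (u[:, None] + rng.normal(0, 0.8, (G, n))).ravel()
        codes = np.repeat(np.arange(G), n)
        X = np.ones((G * n, 1))
        msw = np.mean([np.var(y[codes == g], ddof=1) for g in range(G)])
        group_means = np.array([y[codes == g].mean() for g in range(G)])
        msb = n * np.var(group_means, ddof=1)
        sigma_u2_anova = (msb - msw) / n
        fit = reml_scan(X, y[:, None], [codes], ["Intercept"])
        sigma_e2 = fit.sigma2[0]
        sigma_u2 = fit.ratios[0, 0] * sigma_e2
        assert sigma_e2 == pytest.approx(msw, rel=0.02)
        assert sigma_u2 == pytest.approx(sigma_u2_anova, rel=0.05)

    def test_statsmodels_route_agrees_with_fast_route(self):
        rng = np.random.default_rng(3)
        data = _lmm_frame(rng)
        spec = ModelSpec(formula="correctness*group")
        sm_fit = fit_lmm(spec, data)
        X, names = build_design(data, "correctness*group")
        codes = pd.factorize(data["participant"])[0]
        fast = reml_scan(X, data["amplitude"].to_numpy()[:, None], [codes], names)
        np.testing.assert_allclose(sm_fit.beta, fast.beta[:, 0], atol=0.02)
        np.testing.assert_allclose(sm_fit.se, fast.se[:, 0], rtol=0.08)

    def test_effect_recovery_within_2se(self):
        rng = np.random.default_rng(4)
        beta = 0.05
        rows = []
        for i in range(30):
            u = rng.normal(0, 0.3)
            correct = rng.random(200) < 0.73
            grp = "ssd" if i % 2 else "control"
            y = u + beta * correct + rng.normal(0, 0.5, 200)
            rows.append(pd.DataFrame({
                "participant": f"p{i}", "group": grp,
                "correct": correct.astype(int), "amplitude": y,
            }))
        data = pd.concat(rows, ignore_index=True)
        fit = fit_lmm(ModelSpec(formula="correctness*group"), data)
        i = fit.term_names.index("correctness")
        assert abs(fit.beta[i] - beta) < 2 * fit.se[i]

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(5)
        data = _lmm_frame(rng)
        data["correct"] = 1  # correctness column collinear with intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lmm(ModelSpec(formula="correctness*group"), data)

    def test_single_participant_rejected(self):
        rng = np.random.default_rng(6)
        data = _lmm_frame(rng, n_part=1)
        with pytest.raises(ValueError, match="participants"):
            fit_lmm(ModelSpec(formula="correctness*group"), data)


class TestClusterRuns:
    def test_7_samples_is_a_cluster(self):
        # 7 / 128 = 54.7 ms > 50 ms
        mask = np.zeros(40, dtype=bool)
        mask[10:17] = True
        times = np.arange(40) / 128.0
        assert len(significant_runs(mask, times, fs=128.0)) == 1

    def test_6_samples_is_not(self):
        # 6 / 128 = 46.9 ms
        mask = np.zeros(40, dtype=bool)
        mask[10:16] = True
        times = np.arange(40) / 128.0
        assert significant_runs(mask, times, fs=128.0) == []

    def test_no_significance_empty(self):
        times = np.arange(40) / 128.0
        assert significant_runs(np.zeros(40, dtype=bool), times, 128.0) == []

    def test_peak_is_largest_abs_statistic(self):
        mask = np.zeros(40, dtype=bool)
        mask[5:20] = True
        tstat = np.zeros(40)
        tstat[5:20] = np.linspace(1, 5, 15)
        tstat[12] = -9.0
        times = np.arange(40) / 128.0
        clusters = extract_clusters(mask, tstat, times, 128.0, "correctness", ["Cz"])
        assert len(clusters) == 1
        assert clusters[0].peak_time == pytest.approx(times[12])
        assert clusters[0].peak_stat == -9.0


class TestScan:
    def test_empty_roi_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="region of interest"):
            scan_responsive_electrodes(small_epochs, "correctness", [])

    def test_unknown_roi_channel_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="not present"):
            scan_responsive_electrodes(small_epochs, "correctness", ["XX9"])

    def test_high_snr_recovers_source_electrodes(self, small_epochs):
        grid = scan_responsive_electrodes(
            small_epochs, "correctness",
            roi=["Fz", "FCz", "FC1", "FC2", "Cz", "C1", "C2"])
        assert "Cz" in grid.selected
        assert set(grid.selected) <= {"Cz", "C1", "C2", "FCz", "FC1", "FC2", "Fz"}

    def test_qvalues_dominate_pvalues(self, small_epochs):
        grid = scan_responsive_electrodes(small_epochs, "correctness", ["Cz"])
        assert np.all(grid.qval >= grid.pval - 1e-12)

    def test_confidence_component_sign_recovered(self, small_trials):
        from confclust.synth import (ErpComponentSpec, ErpTemplateSpec,
                                     NoiseSpec, simulate_epochs)

        comp = ErpComponentSpec(
            name="conf", topography={"FCz": 1.0, "FC1": 0.9, "FC2": 0.9},
            peak_latency=0.102, width=0.05, modulator="confidence", gain=4.0,
        )
        ep = simulate_epochs(
            small_trials, ErpTemplateSpec(components=(comp,)),
            NoiseSpec(pink_sd=0.8, white_sd=0.6, intercept_sd=0.5),
            ["Fz", "FCz", "FC1", "FC2", "Cz", "Pz", "POz", "Oz"],
            window=(-0.75, 0.8), rng=np.random.default_rng(23),
        )
        grid = scan_responsive_electrodes(ep, "z_confidence",
                                          roi=["Fz", "FCz", "FC1", "FC2", "Cz"])
        assert "FCz" in grid.selected
        e = grid.electrodes.index("FCz")
        t_i = int(np.argmin(np.abs(grid.times - 0.102)))
        assert grid.coef[e, t_i] > 0

    def test_scan_window_covers_0_to_500ms(self, small_epochs):
        grid = scan_responsive_electrodes(small_epochs, "correctness", ["Cz"])
        assert grid.times[0] == pytest.approx(0.0)
        assert grid.times[-1] == pytest.approx(0.5)


class TestClusterRegressionAndAmplitude:
    def test_cluster_found_at_injected_latency(self, small_epochs):
        cs = cluster_regression(small_epochs, "correctness", ["Cz", "C1", "C2"])
        assert len(cs.clusters) >= 1
        main = max(cs.clusters, key=lambda c: abs(c.peak_stat))
        assert 0.15 <= main.peak_time <= 0.38

    def test_toy_amplitude_hand_computed(self):
        from confclust.epochs import EpochArray

        times = np.arange(0, 64) / 128.0
        data = np.zeros((4, 1, 64))
        data[0, 0, :] = 2.0   # correct
        data[1, 0, :] = 1.0   # correct
        data[2, 0, :] = -1.0  # incorrect
        data[3, 0, :] = 0.5   # incorrect
        meta = pd.DataFrame({
            "participant": ["p0"] * 4, "correct": [1, 1, 0, 0],
            "confidence": [90, 80, 60, 55], "onset": [1, 1.2, 1.4, 1.1],
            "group": ["control"] * 4,
        })
        ep = EpochArray(data=data, times=times, channels=["Cz"], metadata=meta)
        cl = ClusterResult(term="correctness", electrodes=["Cz"], t_start=0.1,
                           t_end=0.3, peak_time=0.2, peak_stat=5.0, n_samples=26)
        mean, sd, per = effect_amplitude(ep, cl, "correctness")
        # hand computation: (2+1)/2 - (-1+0.5)/2 = 1.5 + 0.25 = 1.75
        assert mean == pytest.approx(1.75)

    def test_zero_contrast_zero_amplitude(self):
        from confclust.epochs import EpochArray

        times = np.arange(0, 64) / 128.0
        data = np.ones((4, 1, 64)) * 3.0
        meta = pd.DataFrame({
            "participant": ["p0"] * 4, "correct": [1, 1, 0, 0],
            "confidence": [90, 80, 60, 55], "onset": [1, 1.2, 1.4, 1.1],
            "group": ["control"] * 4,
        })
        ep = EpochArray(data=data, times=times, channels=["Cz"], metadata=meta)
        cl = ClusterResult(term="correctness", electrodes=["Cz"], t_start=0.1,
                           t_end=0.3, peak_time=0.2, peak_stat=5.0, n_samples=26)
        mean, _, _ = effect_amplitude(ep, cl, "correctness")
        assert mean == pytest.approx(0.0)


class TestTertiles:
    def test_nine_distinct_values_equal_split(self):
        labels = assign_tertiles(np.arange(9, dtype=float))
        assert (labels == "low").sum() == 3
        assert (labels == "mid").sum() == 3
        assert (labels == "high").sum() == 3

    def test_all_equal_all_low(self):
        labels = assign_tertiles(np.full(12, 5.0))
        assert np.all(labels == "low")

    def test_one_to_ten_convention(self):
        labels = assign_tertiles(np.arange(1, 11, dtype=float))
        values_by_label = {
            lab: set(np.arange(1, 11)[labels == lab]) for lab in ("low", "mid", "high")
        }
        assert values_by_label["low"] == {1, 2, 3}
        assert values_by_label["mid"] == {4, 5, 6}
        assert values_by_label["high"] == {7, 8, 9, 10}
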