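import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from confclust.metacog import (
    SDTCounts,
    bcis_composite,
    bin_confidence,
    compute_dprime,
    confidence_rt_model,
    counts_from_trials,
    fit_hierarchical_mratio,
    fit_meta_d_mle,
    group_compare,
    profile_loglik,
)
from confclust.metacog.scales import BcisScores


def sdt_trials(rng, n, d, conf_from_evidence=True, conf_noise=0.0):
    stim = rng.choice([-1, 1], n)
    x = rng.normal(stim * d / 2.0, 1.0)
    resp = np.where(x > 0, 1, -1)
    if conf_from_evidence:
        conf = 50 + 12 * np.clip(x * resp, 0, None)
    else:
        conf = rng.uniform(50, 100, n)
    conf = np.clip(conf + rng.normal(0, conf_noise, n), 50, 100)
    return pd.DataFrame({"stimulus": stim, "response": resp, "confidence": conf})


class TestDprime:
    @staticmethod
    def _counts_from_rates(hit, fa, n=1000):
        counts = np.zeros((2, 2, 4))
        counts[1, 1, 0] = hit * n
        counts[1, 0, 0] = (1 - hit) * n
        counts[0, 1, 0] = fa * n
        counts[0, 0, 0] = (1 - fa) * n
        return SDTCounts(counts=counts, n_bins=4)

    def test_chance_gives_zero(self):
        d, c = compute_dprime(self._counts_from_rates(0.5, 0.5))
        assert d == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_inverse_normal_oracle(self):
        # hit 0.8, fa 0.2 -> d' = 2 * Phi^-1(0.8) ~ 1.683
        d, _ = compute_dprime(self._counts_from_rates(0.8, 0.2))
        assert d == pytest.approx(2 * norm.ppf(0.8), abs=1e-9)
        assert d == pytest.approx(1.683, abs=0.001)

    def test_extreme_rates_corrected_finite(self):
        counts = self._counts_from_rates(1.0, 0.2, n=100)
        d, _ = compute_dprime(counts)
        assert np.isfinite(d)
        # hit rate pulled to 1 - 1/(2*100)
        assert d == pytest.approx(norm.ppf(1 - 1 / 200.0) - norm.ppf(0.2), abs=1e-9)


class TestBinning:
    def test_quantile_bins_balanced(self):
        rng = np.random.default_rng(0)
        conf = rng.uniform(50, 100, 1000)
        bins = bin_confidence(conf, 4)
        counts = np.bincount(bins, minlength=4)
        assert counts.min() > 200

    def test_low_confidence_excluded(self):
        trials = pd.DataFrame({
            "stimulus": [1, 1, -1, -1], "response": [1, 1, -1, 1],
            "confidence": [90.0, 30.0, 80.0, 55.0],
        })
        c = counts_from_trials(trials)
        assert c.total == 3  # the 30-confidence trial is excluded


class TestMetaD:
    def test_ideal_observer_mratio_one(self):
        rng = np.random.default_rng(1)
        fit = fit_meta_d_mle(counts_from_trials(sdt_trials(rng, 10_000, 1.2)))
        assert fit.m_ratio == pytest.approx(1.0, abs=0.1)

    def test_scrambled_confidence_meta_d_zero(self):
        rng = np.random.default_rng(2)
        trials = sdt_trials(rng, 8_000, 1.2)
        trials["confidence"] = rng.permutation(trials["confidence"].to_numpy())
        fit = fit_meta_d_mle(counts_from_trials(trials))
        assert abs(fit.meta_d) < 0.15

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            trials = sdt_trials(rng, 1500, rng.uniform(0.8, 1.8),
                                conf_noise=rng.uniform(0, 6))
            counts = counts_from_trials(trials)
            fit = fit_meta_d_mle(counts)
            grid = np.arange(max(fit.meta_d - 0.25, -3), fit.meta_d + 0.25, 0.005)
            lls = [profile_loglik(md, counts, fit.d, fit.criterion) for md in grid]
            md_grid = grid[int(np.argmax(lls))]
            assert abs(fit.meta_d - md_grid) < 0.01

    def test_insufficient_bins_rejected(self):
        counts = np.zeros((2, 2, 4))
        counts[0, 0, 0] = 10
        with pytest.raises(ValueError):
            fit_meta_d_mle(SDTCounts(counts=counts, n_bins=4))


def simulate_counts_from_model(rng, d, c, meta_d, n_trials, k=4, tau_step=0.4):
    """Sample rating counts directly from the response-collapsed meta-d model
    (generative self-consistency oracle for the MLE and the hierarchy)."""
    mc = c * meta_d / d if abs(d) > 1e-9 else c
    taus = mc + np.cumsum(np.full(k - 1, tau_step))
    edges = np.concatenate([[mc], taus, [np.inf]])
    counts = np.zeros((2, 2, k))
    for stim, sign in ((0, -1), (1, 1)):
        n_stim = n_trials // 2
        p_plus = 1 - norm.cdf(c - sign * d / 2)
        n_plus = rng.binomial(n_stim, p_plus)
        mu2 = sign * meta_d / 2
        p = np.diff(norm.cdf(edges - mu2)) / max(1 - norm.cdf(mc - mu2), 1e-12)
        counts[stim, 1] = rng.multinomial(n_plus, p / p.sum())
        edges_m = np.concatenate([[-np.inf], (2 * mc - taus)[::-1], [mc]])
        pm = np.diff(norm.cdf(edges_m - mu2)) / max(norm.cdf(mc - mu2), 1e-12)
        counts[stim, 0] = rng.multinomial(n_stim - n_plus, (pm / pm.sum())[::-1])
    return SDTCounts(counts=counts, n_bins=k)


class TestHierarchy:
    @staticmethod
    def _cohort(rng, n_per_group, mratio_a, mratio_b, n_trials=300):
        counts, groups = {}, {}
        d = 1.3
        for label, m in (("control", mratio_a), ("ssd", mratio_b)):
            for i in range(n_per_group):
                pid = f"{label}{i}"
                counts[pid] = simulate_counts_from_model(
                    rng, d, 0.05, m * d, n_trials)
                groups[pid] = label
        return counts, groups

    def test_matched_groups_recover_regime(self):
        rng = np.random.default_rng(4)
        counts, groups = self._cohort(rng, 8, 0.6, 0.6)
        fit = fit_hierarchical_mratio(counts, groups, seed=5,
                                      n_iter=1200, n_warmup=600)
        for g in ("control", "ssd"):
            assert 0.4 <= fit.group_mean[g] <= 0.8
        assert fit.bf01_difference > 1.0

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(6)
        counts, groups = self._cohort(rng, 10, 1.0, 0.4)
        fit = fit_hierarchical_mratio(counts, groups, seed=7,
                                      n_iter=1200, n_warmup=600)
        assert fit.bf10_difference > 3.0

    def test_shrinkage_between_mle_and_group_mean(self):
        rng = np.random.default_rng(8)
        counts, groups = self._cohort(rng, 6, 0.7, 0.7, n_trials=200)
        fit = fit_hierarchical_mratio(counts, groups, seed=9,
                                      n_iter=1200, n_warmup=600)
        table = fit.participant_table
        for g in ("control", "ssd"):
            mu = float(np.mean(np.log(
                [fit.group_mean[g]])))  # log group-level posterior mean
            sub = table[table["group"] == g]
            for _, row in sub.iterrows():
                theta = fit.theta_means[row["participant"]]
                lo, hi = sorted((row["log_m"], mu))
                assert lo - 0.15 <= theta <= hi + 0.15

    def test_single_participant_group_warns(self):
        rng = np.random.default_rng(10)
        counts, groups = self._cohort(rng, 3, 0.7, 0.7)
        solo = {k: v for k, v in counts.items() if k != "ssd1" and k != "ssd2"}
        solo_groups = {k: groups[k] for k in solo}
        with pytest.warns(UserWarning):
            fit = fit_hierarchical_mratio(solo, solo_groups, seed=11,
                                          n_iter=600, n_warmup=300)
        assert any("prior-dominated" in w for w in fit.warnings)


class TestConfidenceRtModel:
    def test_zero_coupling_all_er_moderate(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(8):
            grp = "ssd" if i % 2 else "control"
            n = 150
            rows.append(pd.DataFrame({
                "participant": f"p{i}", "group": grp,
                "onset": rng.lognormal(0.2, 0.4, n),
                "correct": (rng.random(n) < 0.73).astype(int),
                "confidence": np.clip(rng.normal(70, 10, n), 0, 100),
            }))
        trials = pd.concat(rows, ignore_index=True)
        _, table = confidence_rt_model(trials, n_iter=800, n_warmup=400, seed=13)
        row = table[table["term"] == "z_movementRT"].iloc[0]
        assert 0.02 < row["evidence_ratio"] < 50.0

    def test_sign_recovery(self):
        from confclust.synth import CohortSpec, ObserverSpec, simulate_behavior

        cohort = CohortSpec(n_group_a=6, n_group_b=6,
                            trials_per_participant=150, seed=3)
        obs = ObserverSpec(confidence_rt_coupling=-0.04)
        trials = simulate_behavior(cohort, obs, obs)
        _, table = confidence_rt_model(trials, n_iter=800, n_warmup=400, seed=14)
        row = table[table["term"] == "z_movementRT"].iloc[0]
        assert row["estimate"] < 0
        assert row["evidence_ratio"] > 3


class TestBcis:
    def test_table1_ssd_row(self):
        assert bcis_composite(16.0, 10.3) == pytest.approx(5.7, abs=1e-12)

    def test_table1_control_row(self):
        assert bcis_composite(8.6, 9.5) == pytest.approx(-0.9, abs=1e-12)

    def test_equal_scores_zero(self):
        assert bcis_composite(12.5, 12.5) == 0.0

    def test_dataclass_composite(self):
        assert BcisScores(16.0, 10.3).composite == pytest.approx(5.7, abs=1e-12)


class TestGroupCompare:
    def test_identical_groups(self):
        x = np.arange(10, dtype=float)
        cmp = group_compare(x, x)
        assert cmp.t == pytest.approx(0.0, abs=1e-12)
        assert cmp.bf10 < 1.0

    def test_shifted_groups_large_n(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        cmp = group_compare(a, b)
        assert cmp.bf10 > 3.0
        assert cmp.p < 0.001

    def test_bf_matches_mc_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(16)
        a = rng.normal(0.3, 1, 19)
        b = rng.normal(0.0, 1, 14)
        cmp = group_compare(a, b)
        t_pooled, _ = stats.ttest_ind(a, b, equal_var=True)
        r = np.sqrt(2) / 2
        nu, neff = 31, np.sqrt(19 * 14 / 33)
        delta = stats.cauchy.rvs(0, r, size=1_000_000,
                                 random_state=np.random.default_rng(17))
        mc = stats.nct.pdf(t_pooled, nu, delta * neff).mean() / stats.t.pdf(t_pooled, nu)
        assert cmp.bf10 == pytest.approx(mc, rel=0.01)
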