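"""Regression engines: BH oracle, mixed-model recovery, kernel construction,
cluster-robust covariance."""

import numpy as np
import pandas as pd
import pytest

from photorl.preprocess import EPOCH_POST, EPOCH_PRE, EpochMatrix
from photorl.photometry import PhotometryTrace
from photorl.regression import (KERNEL_CONDITIONS, KERNEL_EVENTS,
                                PointwiseDesign, bh_adjust, cluster_robust_cov,
                                kernel_regression, pointwise_mixed_regression,
                                significance_tier)


def brute_force_bh(p):
    """Step-up BH from the definition: sort, scale by m/rank, enforce
    monotonicity from the largest down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones_unchanged(self):
        assert np.allclose(bh_adjust(np.ones(7)), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(45)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_tiers(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.04) == "0.05"
        assert significance_tier(0.009) == "0.01"
        assert significance_tier(1e-5) == "0.001"


def _make_epochs(n_trials, n_sites, coef, noise, rng, site_sd=0.1):
    """Epochs whose every timepoint follows the same known linear model."""
    sites = np.repeat([f"s{i}" for i in range(n_sites)], n_trials // n_sites)
    choice = (rng.random(n_trials) > 0.5).astype(float)
    value = rng.standard_normal(n_trials)
    site_fx = dict(zip(np.unique(sites), site_sd * rng.standard_normal(n_sites)))
    mu = (coef["intercept"] + coef["choice"] * choice + coef["value"] * value
          + coef["interaction"] * choice * value
          + np.array([site_fx[s] for s in sites]))
    values = mu[:, None] + noise * rng.standard_normal((n_trials, 45))
    ep = EpochMatrix(values=values, time_axis=np.arange(-15, 30) / 15.0,
                     alignment_event="lever_present",
                     trial_index_map=np.arange(n_trials))
    design = PointwiseDesign(choice=choice, value=value, site=sites, frame="chosen")
    return ep, design


class TestPointwiseRegression:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(7)
        coef = {"intercept": 0.1, "choice": 0.5, "value": 0.3, "interaction": 0.0}
        ep, design = _make_epochs(1200, 6, coef, 0.5, rng)
        res = pointwise_mixed_regression(ep, design, random_effects="intercept")
        for term in ("choice", "value", "interaction"):
            tab = res.term(term)
            within = np.abs(tab["coef"] - coef[term]) <= 2.5 * tab["se"]
            assert within.mean() > 0.9

    def test_null_value_rarely_significant_after_bh(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 20
        for _ in range(reps):
            coef = {"intercept": 0.0, "choice": 0.4, "value": 0.0, "interaction": 0.0}
            ep, design = _make_epochs(400, 4, coef, 0.7, rng)
            res = pointwise_mixed_regression(ep, design, random_effects="intercept")
            if (res.term("value")["p_adj"] < 0.05).any():
                hits += 1
        assert hits <= reps * 0.15

    def test_zero_noise_single_effective_site_matches_ols(self):
        rng = np.random.default_rng(9)
        coef = {"intercept": 0.1, "choice": 0.5, "value": 0.3, "interaction": -0.2}
        ep, design = _make_epochs(300, 2, coef, 0.0, rng, site_sd=0.0)
        res = pointwise_mixed_regression(ep, design, random_effects="intercept")
        t0 = res.table[res.table.timepoint == 0].set_index("term")
        for term, val in coef.items():
            assert t0.loc[term, "coef"] == pytest.approx(val, abs=1e-6)

    def test_needs_two_sites(self):
        rng = np.random.default_rng(10)
        ep, design = _make_epochs(100, 1, {"intercept": 0, "choice": 0,
                                           "value": 0, "interaction": 0}, 0.1, rng)
        with pytest.raises(ValueError):
            pointwise_mixed_regression(ep, design)


def _toy_trials_and_traces(rng, n_trials=40, n_sites=2, noise=0.0):
    """Trial tables plus traces built as an exact sum of known condition
    kernels at the three events."""
    from photorl.behavior import TRIAL_COLUMNS

    true_kernels = {}
    for e_i, ev in enumerate(KERNEL_EVENTS):
        for c_i, (side, rew) in enumerate(KERNEL_CONDITIONS):
            amp = 0.2 + 0.1 * e_i + 0.05 * c_i
            kern = amp * np.exp(-np.arange(-EPOCH_PRE, EPOCH_POST) ** 2 / 30.0)
            true_kernels[(ev, side, rew)] = kern

    traces, z_by_site, frames = {}, {}, []
    for s in range(n_sites):
        n = int(15 * (40 + 6 * n_trials))
        z = np.zeros(n)
        rows = []
        t = 30.0
        for i in range(n_trials):
            side = ["contra", "ipsi"][rng.integers(2)]
            prev_side = ["contra", "ipsi"][rng.integers(2)]
            prev_rew = float(rng.integers(2))
            # jittered delays keep the three events' kernels identifiable
            # (constant spacing would make them collinear shifted copies)
            tp = t
            tl = tp + rng.integers(3, 16) / 15.0
            tpress = tl + rng.integers(3, 16) / 15.0
            rows.append(dict(site_id=f"s{s}", session_id="s0", trial_index=i,
                             block_id=0, high_side="contra", choice=side,
                             reward=1.0, prev_choice=prev_side,
                             prev_reward=prev_rew, t_nose_poke=tp,
                             t_lever_present=tl, t_lever_press=tpress,
                             t_outcome=tpress + 0.5, press_latency=tpress - tl,
                             abandoned=False))
            for ev, tt in (("nose_poke", tp), ("lever_present", tl),
                           ("lever_press", tpress)):
                k = int(round(tt * 15))
                kern = true_kernels[(ev, side, prev_rew)]
                z[k - EPOCH_PRE:k + EPOCH_POST] += kern
            t += 6.0
        z += noise * rng.standard_normal(n)
        traces[f"s{s}"] = PhotometryTrace(site_id=f"s{s}", sampling_rate=15.0,
                                          samples=100 * (1 + z))
        z_by_site[f"s{s}"] = z
        frames.append(pd.DataFrame(rows, columns=TRIAL_COLUMNS))
    trials = pd.concat(frames, ignore_index=True)
    return traces, z_by_site, trials, true_kernels


class TestKernelRegression:
    def test_exact_recovery_on_noise_free_construction(self):
        rng = np.random.default_rng(11)
        traces, z, trials, truth = _toy_trials_and_traces(rng)
        fit = kernel_regression(traces, z, trials)
        tab = fit.table
        for (ev, side, rew), kern in truth.items():
            cond = f"{side}:{'prev_rew' if rew == 1.0 else 'prev_unrew'}"
            got = tab[(tab.event == ev) & (tab.condition == cond)]["coef"].to_numpy()
            assert np.allclose(got, kern, atol=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_trace_gives_zero_kernels(self):
        rng = np.random.default_rng(12)
        traces, z, trials, _ = _toy_trials_and_traces(rng)
        z0 = {k: np.zeros_like(v) for k, v in z.items()}
        fit = kernel_regression(traces, z0, trials)
        assert np.allclose(fit.table["coef"], 0.0, atol=1e-10)


class TestClusterRobustCov:
    def _xy(self, rng, n=600, k=3):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        return X

    def test_iid_residuals_match_classical(self):
        rng = np.random.default_rng(13)
        X = self._xy(rng)
        n = X.shape[0]
        ratios = []
        for _ in range(30):
            resid = rng.standard_normal(n)
            clusters = np.arange(n)  # one observation per cluster
            cr = cluster_robust_cov(X, resid, clusters)
            s2 = resid @ resid / (n - X.shape[1])
            classical = s2 * np.linalg.inv(X.T @ X)
            ratios.append(np.sqrt(np.diag(cr)) / np.sqrt(np.diag(classical)))
        assert np.allclose(np.mean(ratios, axis=0), 1.0, atol=0.1)

    def test_correlated_clusters_inflate_se(self):
        rng = np.random.default_rng(14)
        n, g = 600, 6
        clusters = np.repeat(np.arange(g), n // g)
        X = np.column_stack([np.ones(n),
                             np.repeat(rng.standard_normal(g), n // g)])
        resid = np.repeat(rng.standard_normal(g), n // g)  # perfectly correlated
        cr = cluster_robust_cov(X, resid, clusters)
        s2 = resid @ resid / (n - 2)
        classical = s2 * np.linalg.inv(X.T @ X)
        assert np.sqrt(cr[1, 1]) > np.sqrt(classical[1, 1])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(15)
        X = self._xy(rng, n=200)
        resid = rng.standard_normal(200)
        clusters = np.repeat(np.arange(10), 20)
        cov = cluster_robust_cov(X, resid, clusters)
        assert np.allclose(cov, cov.T)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-12

    def test_matches_statsmodels_cluster_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(16)
        n, g = 400, 8
        X = self._xy(rng, n=n)
        beta = np.array([0.5, -0.3, 0.2])
        clusters = np.repeat(np.arange(g), n // g)
        y = X @ beta + rng.standard_normal(n) + np.repeat(rng.standard_normal(g), n // g)
        ols = sm.OLS(y, X).fit()
        smc = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": clusters}).bse
        ours = np.sqrt(np.diag(cluster_robust_cov(X, ols.resid, clusters)))
        # statsmodels uses a slightly different small-sample correction
        assert np.allclose(ours, smc, rtol=0.15)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_robust_cov(np.ones((10, 1)), np.zeros(10), np.zeros(10))
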