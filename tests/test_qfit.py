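"""Likelihood oracles, parameter recovery, convergence diagnostics, Q trajectories."""

import numpy as np
import pandas as pd
import pytest

from photorl.behavior import (AgentParams, TaskConfig, choice_prob,
                              simulate_cohort, simulate_site, stay_fraction)
from photorl.pipeline import GROUP_MEDIANS
from photorl.qfit import (FitConfig, compute_q_trajectories, fit_hierarchical,
                          fit_subject, negloglik, rhat)


def brute_force_negloglik(params, trials):
    """Independent re-derivation: trial-by-trial probability via choice_prob
    and explicit Q bookkeeping in a dict."""
    q = {"contra": 0.0, "ipsi": 0.0}
    nll = 0.0
    for _, row in trials.iterrows():
        if row.abandoned:
            continue
        pc = choice_prob(q["contra"], q["ipsi"], row.prev_choice, params)
        p = pc if row.choice == "contra" else 1 - pc
        nll -= np.log(p)
        q[row.choice] += params.alpha * (row.reward - q[row.choice])
    return nll


class TestNegloglik:
    def test_uniform_policy_is_n_log_2(self, site_trials):
        n = int((~site_trials.abandoned).sum())
        params = AgentParams(alpha=0.5, beta=0.0, stay=0.0)
        assert negloglik(params, site_trials) == pytest.approx(n * np.log(2))

    def test_two_trial_hand_computation(self):
        rows = []
        for i, (c, r) in enumerate([("contra", 1.0), ("contra", 0.0)]):
            rows.append(dict(site_id="s", session_id="s0", trial_index=i,
                             block_id=0, high_side="contra", choice=c, reward=r,
                             prev_choice="none" if i == 0 else "contra",
                             prev_reward=np.nan if i == 0 else 1.0,
                             t_nose_poke=i * 10.0, t_lever_present=i * 10 + 0.5,
                             t_lever_press=i * 10 + 1.0, t_outcome=i * 10 + 1.5,
                             press_latency=0.5, abandoned=False))
        trials = pd.DataFrame(rows)
        params = AgentParams(alpha=0.5, beta=1.0, stay=0.0)
        # trial 1: P = 0.5; trial 2: Q_contra = 0.5 -> P = logistic(0.5)
        expected = -np.log(0.5) - np.log(1 / (1 + np.exp(-0.5)))
        assert negloglik(params, trials) == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self, site_trials):
        for params in (GROUP_MEDIANS, AgentParams(0.3, 2.0, -0.5)):
            assert negloglik(params, site_trials) == pytest.approx(
                brute_force_negloglik(params, site_trials), rel=1e-10)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            negloglik(GROUP_MEDIANS, pd.DataFrame(columns=["abandoned"]))


@pytest.fixture(scope="module")
def recovery_trials():
    task = TaskConfig(trials_per_session=250, sessions_per_site=4)
    true = AgentParams(alpha=0.6, beta=1.0, stay=0.9)
    return true, simulate_site(true, task, np.random.default_rng(21))


class TestFitSubject:
    def test_parameter_recovery_1000_trials(self, recovery_trials):
        true, trials = recovery_trials
        est, _ = fit_subject(trials)
        assert est.alpha == pytest.approx(true.alpha, abs=0.15)
        assert est.beta == pytest.approx(true.beta, abs=0.3)
        assert est.stay == pytest.approx(true.stay, abs=0.3)

    def test_fitted_nll_not_worse_than_truth(self, recovery_trials):
        true, trials = recovery_trials
        est, nll = fit_subject(trials)
        assert nll <= negloglik(true, trials) + 1e-6

    def test_few_trials_warns(self, site_trials):
        with pytest.warns(UserWarning):
            fit_subject(site_trials.iloc[:30])


class TestRhat:
    def test_identical_stationary_chains_near_one(self):
        # split-chain Rhat compares half-chains, so even byte-identical
        # stationary chains sit at 1 only up to within-chain sampling noise
        x = np.random.default_rng(0).standard_normal(500)
        assert rhat(np.vstack([x, x])) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_constant_chains_diverge(self):
        chains = np.vstack([np.zeros(100), np.ones(100)])
        assert rhat(chains) > 10

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        vals = [rhat(rng.standard_normal((4, 750))) for _ in range(20)]
        assert np.median(vals) < 1.003
        assert max(vals) < 1.01

    def test_matches_arviz_on_iid_draws(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 750))
        ours = rhat(x)
        theirs = az.rhat(az.convert_to_dataset(x[:, :, None]))["x"].values.item()
        assert ours == pytest.approx(theirs, abs=0.005)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestHierarchical:
    def test_single_subject_rejected(self, site_trials):
        with pytest.raises(ValueError):
            fit_hierarchical(site_trials, FitConfig(method="hierarchical_map"))

    def test_identical_subjects_shrink_group_variance(self):
        task = TaskConfig(trials_per_session=250, sessions_per_site=2)
        trials = simulate_cohort([GROUP_MEDIANS] * 6, task, seed=31)
        res = fit_hierarchical(trials, FitConfig(method="hierarchical_map",
                                                 n_chains=1, rng_seed=0))
        pct = res.group_percentiles
        assert pct.loc["alpha", "p50"] == pytest.approx(GROUP_MEDIANS.alpha, abs=0.08)
        assert pct.loc["beta", "p50"] == pytest.approx(GROUP_MEDIANS.beta, abs=0.2)
        assert pct.loc["stay", "p50"] == pytest.approx(GROUP_MEDIANS.stay, abs=0.2)
        # identical generators: fitted subject spread stays narrow
        assert pct.loc["alpha", "p75"] - pct.loc["alpha", "p25"] < 0.2

    def test_mcmc_and_map_subject_estimates_agree(self):
        # backend agreement is only expected where the data identify the
        # parameters well; a sharper (higher-beta) agent gives near-Gaussian
        # subject posteriors whose mode and median coincide
        task = TaskConfig(trials_per_session=375, sessions_per_site=4)
        sharp = AgentParams(alpha=0.5, beta=1.5, stay=0.7)
        trials = simulate_cohort([sharp] * 4, task, seed=32)
        res_map = fit_hierarchical(trials, FitConfig(method="hierarchical_map",
                                                     n_chains=1, rng_seed=0))
        res_mcmc = fit_hierarchical(trials, FitConfig(method="hierarchical_mcmc",
                                                      rng_seed=0,
                                                      keep_samples=False))
        for site in res_map.subject_params:
            pm, pc = res_map.subject_params[site], res_mcmc.subject_params[site]
            assert pm.alpha == pytest.approx(pc.alpha, abs=0.05)
            assert pm.beta == pytest.approx(pc.beta, abs=0.1)
            assert pm.stay == pytest.approx(pc.stay, abs=0.1)

    def test_posterior_predictive_stay_fraction(self):
        task = TaskConfig(trials_per_session=250, sessions_per_site=3)
        trials = simulate_cohort([GROUP_MEDIANS] * 4, task, seed=33)
        res = fit_hierarchical(trials, FitConfig(method="per_subject_mle",
                                                 n_chains=1, rng_seed=0))
        sim = simulate_cohort([res.subject_params[f"site{i}"] for i in range(4)],
                              task, seed=34)
        assert stay_fraction(sim) == pytest.approx(stay_fraction(trials), abs=0.03)


class TestQTrajectories:
    def test_first_trial_dq_is_zero(self, site_qtraj):
        assert site_qtraj.iloc[0]["dq_chosen"] == 0.0
        assert site_qtraj.iloc[0]["dq_contra"] == 0.0

    def test_sign_identity_between_frames(self, site_trials, site_qtraj):
        done = ~site_trials.abandoned
        sign = np.where(site_trials.loc[done, "choice"] == "contra", 1.0, -1.0)
        assert np.allclose(site_qtraj.loc[done, "dq_chosen"],
                           sign * site_qtraj.loc[done, "dq_contra"])

    def test_q_values_bounded_for_binary_rewards(self, site_qtraj):
        assert site_qtraj["q_contra"].between(0, 1).all()
        assert site_qtraj["q_ipsi"].between(0, 1).all()

    def test_standardized_columns_per_site(self, cohort_trials):
        qtraj = compute_q_trajectories(
            {f"site{i}": GROUP_MEDIANS for i in range(3)}, cohort_trials)
        for site, df in cohort_trials.groupby("site_id"):
            vals = qtraj.loc[df.index, "dq_chosen_std"].dropna()
            assert vals.mean() == pytest.approx(0, abs=1e-9)
            assert vals.std(ddof=0) == pytest.approx(1, abs=1e-9)

    def test_missing_subject_rejected(self, cohort_trials):
        with pytest.raises(ValueError):
            compute_q_trajectories({"site0": GROUP_MEDIANS}, cohort_trials)
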