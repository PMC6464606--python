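"""Fitting the Q-learning model to choice data.

Three backends share one likelihood (JIT-compiled, see
:mod:`photorl._likelihood`):

``per_subject_mle``
    independent maximum-likelihood fits per site, multi-start quasi-Newton
    on unconstrained scales (logit alpha, log beta, raw stay).
``hierarchical_map``
    joint maximum a posteriori over subject parameters plus group-level
    means and SDs (Gaussian random effects on the unconstrained scales).
``hierarchical_mcmc``
    full posterior via a slice-within-Gibbs sampler: stepping-out slice
    updates for every subject coordinate, conjugate draws for the group
    means, slice updates for the group log-SDs. Convergence is diagnosed
    with the split-chain potential scale reduction statistic (Rhat).

Group-level priors: means ~ Normal(0, 1.5) and SDs ~ HalfNormal(1) on the
unconstrained scales; the scale of published fits of this model (alpha ~ 0.6,
beta ~ 1, stay ~ 0.95) sits comfortably inside this prior mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _likelihood as lk
from .behavior import CONTRA, IPSI, NONE, AgentParams

__all__ = [
    "FitConfig",
    "FitResult",
    "FitFailure",
    "negloglik",
    "fit_subject",
    "fit_hierarchical",
    "rhat",
    "compute_q_trajectories",
]

_MU_PRIOR_SD = 1.5
_SIGMA_PRIOR_SD = 1.0
_PARAM_NAMES = ("alpha", "beta", "stay")


class FitFailure(RuntimeError):
    """Raised when every optimizer restart fails to converge."""


@dataclass
class FitConfig:
    """Controls for the model fit (defaults follow common Stan practice for
    this model: 4 chains x 1000 iterations, 250 warmup)."""

    method: str = "hierarchical_mcmc"
    n_chains: int = 4
    n_iter: int = 1000
    n_warmup: int = 250
    target_accept: float = 0.99  # kept for config-file compatibility; the slice sampler has no accept rate
    rng_seed: int = 0
    rhat_threshold: float = 1.003
    keep_samples: bool = True

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ValueError("n_warmup must be < n_iter")
        if self.method == "hierarchical_mcmc" and self.n_chains < 2:
            raise ValueError("hierarchical_mcmc needs >= 2 chains")


@dataclass
class FitResult:
    subject_params: dict
    group_percentiles: pd.DataFrame
    group_mean_percentiles: pd.DataFrame | None
    rhat: dict
    loglik: float
    samples: dict | None = None
    warnings: list = field(default_factory=list)

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


# ---------------------------------------------------------------------------
# data encoding


def _encode_site(trials: pd.DataFrame):
    done = trials.loc[~trials["abandoned"].astype(bool)]
    choice = (done["choice"] == CONTRA).to_numpy(dtype=np.int8)
    reward = done["reward"].to_numpy(dtype=np.float64)
    prev = np.where(
        done["prev_choice"] == CONTRA, 1,
        np.where(done["prev_choice"] == IPSI, 0, -1),
    ).astype(np.int8)
    return choice, reward, prev


def _encode_cohort(trials: pd.DataFrame):
    sites, chs, rws, pvs = [], [], [], []
    offsets = [0]
    for site_id, df in trials.groupby("site_id", sort=False):
        c, r, p = _encode_site(df)
        sites.append(site_id)
        chs.append(c)
        rws.append(r)
        pvs.append(p)
        offsets.append(offsets[-1] + len(c))
    return (
        sites,
        np.concatenate(chs),
        np.concatenate(rws),
        np.concatenate(pvs),
        np.asarray(offsets, dtype=np.int64),
    )


def _to_natural(x: np.ndarray) -> AgentParams:
    return AgentParams(alpha=float(expit(x[0])), beta=float(np.exp(x[1])), stay=float(x[2]))


def _to_unconstrained(p: AgentParams) -> np.ndarray:
    a = min(max(p.alpha, 1e-6), 1 - 1e-6)
    return np.array([logit(a), np.log(max(p.beta, 1e-6)), p.stay])


# ---------------------------------------------------------------------------
# likelihood and per-subject MLE


def negloglik(params: AgentParams, trials: pd.DataFrame) -> float:
    """Negative log-likelihood of one site's completed trials under the
    Q recursion (Q initialized at 0, stay indicator from ``prev_choice``)."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    choice, reward, prev = _encode_site(trials)
    if len(choice) == 0:
        raise ValueError("no completed trials")
    return float(lk.negloglik_natural(params.alpha, params.beta, params.stay,
                                      choice, reward, prev))


def fit_subject(
    trials: pd.DataFrame,
    config: FitConfig | None = None,
    n_starts: int = 5,
) -> tuple[AgentParams, float]:
    """Multi-start MLE for one site. Returns (params, negative log-likelihood)."""
    config = config or FitConfig(method="per_subject_mle", n_chains=1)
    choice, reward, prev = _encode_site(trials)
    if len(choice) == 0:
        raise ValueError("no completed trials")
    if len(choice) < 50:
        warnings.warn(f"only {len(choice)} trials; estimates may be unstable")
    rng = np.random.default_rng(config.rng_seed)

    def nll(x):
        return lk.negloglik_unconstrained(x[0], x[1], x[2], choice, reward, prev)

    starts = [np.zeros(3)]
    starts += [rng.normal(0.0, 1.0, size=3) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailure("all optimizer restarts failed")
    return _to_natural(best.x), float(best.fun)


# ---------------------------------------------------------------------------
# hierarchical backends


def _neg_logpost_flat(vec, choice, reward, prev, offsets, S):
    mu = vec[:3]
    log_sigma = vec[3:6]
    sigma = np.exp(log_sigma)
    thetas = vec[6:].reshape(S, 3)
    nlp = lk.total_negloglik(thetas, choice, reward, prev, offsets)
    z = (thetas - mu) / sigma
    nlp += 0.5 * float(np.sum(z * z)) + S * float(np.sum(log_sigma))
    nlp += 0.5 * float(np.sum((mu / _MU_PRIOR_SD) ** 2))
    nlp += float(np.sum(0.5 * (sigma / _SIGMA_PRIOR_SD) ** 2 - log_sigma))
    return nlp


def _slice1d(logp, x0, rng, w=0.5, max_step=20):
    ly = logp(x0) - rng.exponential(1.0)
    u = rng.uniform()
    L, R = x0 - w * u, x0 - w * u + w
    j = 0
    while j < max_step and logp(L) > ly:
        L -= w
        j += 1
    j = 0
    while j < max_step and logp(R) > ly:
        R += w
        j += 1
    while True:
        x1 = rng.uniform(L, R)
        if logp(x1) >= ly:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


def _init_subject_mles(trials: pd.DataFrame, seed: int) -> dict:
    out = {}
    for site_id, df in trials.groupby("site_id", sort=False):
        params, _ = fit_subject(df, FitConfig(method="per_subject_mle",
                                              n_chains=1, rng_seed=seed))
        out[site_id] = params
    return out


def _percentile_frame(d: dict) -> pd.DataFrame:
    return pd.DataFrame(d, index=["p25", "p50", "p75"]).T.loc[list(_PARAM_NAMES)]


def _natural(j: int, x: np.ndarray) -> np.ndarray:
    if j == 0:
        return expit(x)
    if j == 1:
        return np.exp(x)
    return x


def fit_hierarchical(trials: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit all sites jointly with Gaussian random effects on the
    unconstrained parameter scales.

    ``group_percentiles`` reports the 25th/50th/75th percentiles of the
    *implied subject-level distribution* on the natural scales (the format of
    published group-level tables for this model); ``group_mean_percentiles``
    reports posterior percentiles of the transformed group means (MCMC only).
    """
    config = config or FitConfig()
    sites, choice, reward, prev, offsets = _encode_cohort(trials)
    S = len(sites)
    if S < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects")

    if config.method == "per_subject_mle":
        return _fit_all_mle(trials, sites, config)
    if config.method == "hierarchical_map":
        return _fit_map(trials, sites, choice, reward, prev, offsets, config)
    if config.method == "hierarchical_mcmc":
        return _fit_mcmc(trials, sites, choice, reward, prev, offsets, config)
    raise ValueError(f"unknown method {config.method!r}")


def _fit_all_mle(trials, sites, config):
    subject_params = _init_subject_mles(trials, config.rng_seed)
    thetas = np.array([_to_unconstrained(subject_params[s]) for s in sites])
    pct = {}
    for j, name in enumerate(_PARAM_NAMES):
        vals = _natural(j, thetas[:, j])
        pct[name] = np.percentile(vals, [25, 50, 75])
    sites_, choice, reward, prev, offsets = _encode_cohort(trials)
    ll = -float(lk.total_negloglik(thetas, choice, reward, prev, offsets))
    return FitResult(subject_params=subject_params,
                     group_percentiles=_percentile_frame(pct),
                     group_mean_percentiles=None, rhat={}, loglik=ll)


def _map_point(trials, sites, choice, reward, prev, offsets, config):
    S = len(sites)
    mles = _init_subject_mles(trials, config.rng_seed)
    theta0 = np.array([_to_unconstrained(mles[s]) for s in sites])
    mu0 = theta0.mean(axis=0)
    sig0 = np.clip(theta0.std(axis=0, ddof=1), 0.05, None)
    vec0 = np.concatenate([mu0, np.log(sig0), theta0.ravel()])
    # joint MAP of a hierarchical model is degenerate at sigma -> 0; keep the
    # group SDs bounded away from the collapse (documented in the methods note)
    bounds = ([(None, None)] * 3 + [(np.log(0.02), np.log(2.0))] * 3
              + [(None, None)] * (3 * S))
    res = minimize(_neg_logpost_flat, vec0, bounds=bounds,
                   args=(choice, reward, prev, offsets, S), method="L-BFGS-B",
                   options={"maxiter": 2000})
    mu = res.x[:3]
    sigma = np.exp(res.x[3:6])
    thetas = res.x[6:].reshape(S, 3)
    return mu, sigma, thetas


def _fit_map(trials, sites, choice, reward, prev, offsets, config):
    mu, sigma, thetas = _map_point(trials, sites, choice, reward, prev, offsets, config)
    subject_params = {s: _to_natural(thetas[i]) for i, s in enumerate(sites)}
    zq = {"p25": -0.6744897501960817, "p50": 0.0, "p75": 0.6744897501960817}
    pct = {}
    for j, name in enumerate(_PARAM_NAMES):
        pct[name] = [float(_natural(j, np.array([mu[j] + z * sigma[j]]))[0])
                     for z in zq.values()]
    ll = -float(lk.total_negloglik(thetas, choice, reward, prev, offsets))
    return FitResult(subject_params=subject_params,
                     group_percentiles=_percentile_frame(pct),
                     group_mean_percentiles=None, rhat={}, loglik=ll,
                     warnings=["MAP backend: no sampler, Rhat not available"])


def _fit_mcmc(trials, sites, choice, reward, prev, offsets, config):
    S = len(sites)
    n_keep = config.n_iter - config.n_warmup
    # initialize chains from the per-subject MLE spread (the joint MAP
    # over-shrinks the group SDs, a poor place to start the Gibbs sweep)
    mles = _init_subject_mles(trials, config.rng_seed)
    theta0 = np.array([_to_unconstrained(mles[s]) for s in sites])
    mu0 = theta0.mean(axis=0)
    sig0 = np.clip(theta0.std(axis=0, ddof=1), 0.05, None)

    master = np.random.SeedSequence(config.rng_seed)
    children = master.spawn(config.n_chains)

    mu_draws = np.empty((config.n_chains, n_keep, 3))
    sigma_draws = np.empty((config.n_chains, n_keep, 3))
    theta_draws = np.empty((config.n_chains, n_keep, S, 3))

    prec0 = 1.0 / _MU_PRIOR_SD**2
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        lk.seed_kernel_rng(int(child.generate_state(1)[0] % 2**31))
        thetas = theta0 + 0.05 * rng.standard_normal(theta0.shape)
        mu = mu0 + 0.05 * rng.standard_normal(3)
        sigma = sig0.copy()
        for it in range(config.n_iter):
            lk.update_subjects_slice(thetas, mu, sigma, choice, reward, prev,
                                     offsets, 0.3, 50)
            for j in range(3):
                prec = prec0 + S / sigma[j] ** 2
                mean = (thetas[:, j].sum() / sigma[j] ** 2) / prec
                mu[j] = mean + rng.standard_normal() / math.sqrt(prec)

                dev2 = float(np.sum((thetas[:, j] - mu[j]) ** 2))

                def logp_logsig(ls, dev2=dev2):
                    s2 = math.exp(2 * ls)
                    return (-S * ls - dev2 / (2 * s2)
                            - s2 / (2 * _SIGMA_PRIOR_SD**2) + ls)

                sigma[j] = math.exp(_slice1d(logp_logsig, math.log(sigma[j]), rng))
            # interweaved non-centered update of the group parameters (ASIS)
            lk.update_group_noncentered(thetas, mu, sigma, choice, reward, prev,
                                        offsets, _MU_PRIOR_SD, _SIGMA_PRIOR_SD,
                                        0.3, 50)
            if it >= config.n_warmup:
                k = it - config.n_warmup
                mu_draws[c, k] = mu
                sigma_draws[c, k] = sigma
                theta_draws[c, k] = thetas

    # convergence diagnostics over every sampled parameter
    rh = {}
    for j, name in enumerate(_PARAM_NAMES):
        rh[f"mu_{name}"] = rhat(mu_draws[:, :, j])
        rh[f"sigma_{name}"] = rhat(sigma_draws[:, :, j])
        for i, site in enumerate(sites):
            rh[f"{name}[{site}]"] = rhat(theta_draws[:, :, i, j])

    warns = []
    bad = {k: v for k, v in rh.items() if v > config.rhat_threshold}
    if bad:
        warns.append(f"Rhat above {config.rhat_threshold} for: {sorted(bad)}")

    # subject point estimates: posterior medians on the natural scales
    subject_params = {}
    for i, site in enumerate(sites):
        vals = [float(np.median(_natural(j, theta_draws[:, :, i, j].ravel())))
                for j in range(3)]
        subject_params[site] = AgentParams(alpha=min(max(vals[0], 0.0), 1.0),
                                           beta=max(vals[1], 0.0), stay=vals[2])

    zq = [-0.6744897501960817, 0.0, 0.6744897501960817]
    pct, pct_mean = {}, {}
    for j, name in enumerate(_PARAM_NAMES):
        mu_flat = mu_draws[:, :, j].ravel()
        sd_flat = sigma_draws[:, :, j].ravel()
        pct[name] = [float(np.median(_natural(j, mu_flat + z * sd_flat))) for z in zq]
        pct_mean[name] = np.percentile(_natural(j, mu_flat), [25, 50, 75])

    theta_med = np.array([_to_unconstrained(subject_params[s]) for s in sites])
    ll = -float(lk.total_negloglik(theta_med, choice, reward, prev, offsets))

    samples = None
    if config.keep_samples:
        samples = {"mu": mu_draws, "sigma": sigma_draws, "theta": theta_draws,
                   "sites": sites}
    return FitResult(subject_params=subject_params,
                     group_percentiles=_percentile_frame(pct),
                     group_mean_percentiles=_percentile_frame(pct_mean),
                     rhat=rh, loglik=ll, samples=samples, warnings=warns)


# ---------------------------------------------------------------------------
# diagnostics


def rhat(samples: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter.

    ``samples`` has shape (n_chains, n_draws); each chain is split in half,
    and Rhat = sqrt(((n-1)/n * W + B/n) / W) over the 2*m half-chains.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = samples.shape
    half = n // 2
    split = np.vstack([samples[:, :half], samples[:, half:2 * half]])
    n = half
    means = split.mean(axis=1)
    W = float(np.mean(split.var(axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return float("inf") if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Q trajectories


def compute_q_trajectories(
    subject_params: dict,
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Forward-simulate the Q recursion on observed choices/rewards.

    Returns a DataFrame aligned row-for-row with ``trials`` carrying the
    pre-update action values (``q_contra``, ``q_ipsi``), the value
    differences in both reference frames (``dq_chosen`` = Q(chosen) -
    Q(unchosen); ``dq_contra`` = Q(contra) - Q(ipsi)), and per-site
    standardized versions of each. Abandoned trials get NaN differences and
    do not update Q.
    """
    missing = set(trials["site_id"].unique()) - set(subject_params)
    if missing:
        raise ValueError(f"no fitted parameters for sites: {sorted(missing)}")

    out = pd.DataFrame(
        index=trials.index,
        columns=["q_contra", "q_ipsi", "dq_chosen", "dq_contra",
                 "dq_chosen_std", "dq_contra_std"],
        dtype=float,
    )
    for site_id, df in trials.groupby("site_id", sort=False):
        p = subject_params[site_id]
        qc = qi = 0.0
        for idx, row in df.iterrows():
            out.at[idx, "q_contra"] = qc
            out.at[idx, "q_ipsi"] = qi
            if row["abandoned"]:
                continue
            dqc = qc - qi
            out.at[idx, "dq_contra"] = dqc
            out.at[idx, "dq_chosen"] = dqc if row["choice"] == CONTRA else -dqc
            if row["choice"] == CONTRA:
                qc = qc + p.alpha * (row["reward"] - qc)
            else:
                qi = qi + p.alpha * (row["reward"] - qi)
        for col in ("dq_chosen", "dq_contra"):
            vals = out.loc[df.index, col]
            sd = vals.std(ddof=0)
            if sd > 0:
                out.loc[df.index, col + "_std"] = (vals - vals.mean()) / sd
            else:
                out.loc[df.index, col + "_std"] = 0.0
    return out
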