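"""Numba kernels for the Q-learning likelihood and the hierarchical sampler.

Data layout: per-subject trial sequences are concatenated into flat arrays
(``choice`` int8 with 1 = contra / 0 = ipsi, ``reward`` float64, ``prev``
int8 with 1/0/-1 for contra/ipsi/none) indexed by ``offsets`` (length
n_subjects + 1). Subject parameters live on unconstrained scales:
x = (logit alpha, log beta, stay).
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _softplus(z):
    # log(1 + exp(z)), stable
    if z > 0.0:
        return z + np.log1p(np.exp(-z))
    return np.log1p(np.exp(z))


@njit(cache=False)
def negloglik_natural(alpha, beta, stay, choice, reward, prev):
    """-sum_t log P(c_t) under the Q recursion, natural parameter scale."""
    qc = 0.0
    qi = 0.0
    nll = 0.0
    for t in range(choice.shape[0]):
        s = 0.0
        if prev[t] == 1:
            s = stay
        elif prev[t] == 0:
            s = -stay
        x = beta * (qc - qi) + s
        if choice[t] == 1:
            nll += _softplus(-x)
            qc += alpha * (reward[t] - qc)
        else:
            nll += _softplus(x)
            qi += alpha * (reward[t] - qi)
    return nll


@njit(cache=False)
def negloglik_unconstrained(x1, x2, x3, choice, reward, prev):
    alpha = 1.0 / (1.0 + np.exp(-x1))
    beta = np.exp(x2)
    return negloglik_natural(alpha, beta, x3, choice, reward, prev)


@njit(cache=False)
def total_negloglik(thetas, choice, reward, prev, offsets):
    """Sum of per-subject negative log-likelihoods; thetas is (S, 3) unconstrained."""
    out = 0.0
    for s in range(thetas.shape[0]):
        a, b = offsets[s], offsets[s + 1]
        out += negloglik_unconstrained(
            thetas[s, 0], thetas[s, 1], thetas[s, 2],
            choice[a:b], reward[a:b], prev[a:b],
        )
    return out


@njit(cache=False)
def _subject_logpost(theta_s, choice, reward, prev, mu, sigma):
    lp = -negloglik_unconstrained(theta_s[0], theta_s[1], theta_s[2],
                                  choice, reward, prev)
    for j in range(3):
        z = (theta_s[j] - mu[j]) / sigma[j]
        lp += -0.5 * z * z - np.log(sigma[j])
    return lp


@njit(cache=False)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _nc_logpost(j, muj, logsigj, raw, thetas, choice, reward, prev, offsets,
                mu_prior_sd, sig_prior_sd):
    """Log posterior of (mu_j, log sigma_j) in the non-centered
    parameterization, holding raw_j = (theta_j - mu_j)/sigma_j fixed."""
    sig = np.exp(logsigj)
    ll = 0.0
    for s in range(thetas.shape[0]):
        t0 = thetas[s, 0]
        t1 = thetas[s, 1]
        t2 = thetas[s, 2]
        v = muj + sig * raw[s]
        if j == 0:
            t0 = v
        elif j == 1:
            t1 = v
        else:
            t2 = v
        a, b = offsets[s], offsets[s + 1]
        ll -= negloglik_unconstrained(t0, t1, t2, choice[a:b], reward[a:b], prev[a:b])
    return (ll - 0.5 * (muj / mu_prior_sd) ** 2
            - 0.5 * (sig / sig_prior_sd) ** 2 + logsigj)


@njit(cache=False)
def update_group_noncentered(thetas, mu, sigma, choice, reward, prev, offsets,
                             mu_prior_sd, sig_prior_sd, w, max_step):
    """ASIS interweaving step: re-sample each (mu_j, log sigma_j) with the
    standardized subject deviations held fixed, then rebuild thetas. Breaks
    the slow coupling between group scales and subject parameters in the
    centered Gibbs sweep. Mutates mu, sigma and thetas in place."""
    S = thetas.shape[0]
    raw = np.empty(S)
    for j in range(3):
        for s in range(S):
            raw[s] = (thetas[s, j] - mu[j]) / sigma[j]
        # slice over mu_j
        x0 = mu[j]
        ls0 = np.log(sigma[j])
        ly = _nc_logpost(j, x0, ls0, raw, thetas, choice, reward, prev, offsets,
                         mu_prior_sd, sig_prior_sd) - np.random.exponential(1.0)
        u = np.random.uniform(0.0, 1.0)
        L = x0 - w * u
        R = L + w
        k = 0
        while k < max_step and _nc_logpost(j, L, ls0, raw, thetas, choice, reward,
                                           prev, offsets, mu_prior_sd, sig_prior_sd) > ly:
            L -= w
            k += 1
        k = 0
        while k < max_step and _nc_logpost(j, R, ls0, raw, thetas, choice, reward,
                                           prev, offsets, mu_prior_sd, sig_prior_sd) > ly:
            R += w
            k += 1
        while True:
            x1 = np.random.uniform(L, R)
            if _nc_logpost(j, x1, ls0, raw, thetas, choice, reward, prev, offsets,
                           mu_prior_sd, sig_prior_sd) >= ly:
                mu[j] = x1
                break
            if x1 < x0:
                L = x1
            else:
                R = x1
        # slice over log sigma_j
        x0 = ls0
        ly = _nc_logpost(j, mu[j], x0, raw, thetas, choice, reward, prev, offsets,
                         mu_prior_sd, sig_prior_sd) - np.random.exponential(1.0)
        u = np.random.uniform(0.0, 1.0)
        L = x0 - w * u
        R = L + w
        k = 0
        while k < max_step and _nc_logpost(j, mu[j], L, raw, thetas, choice, reward,
                                           prev, offsets, mu_prior_sd, sig_prior_sd) > ly:
            L -= w
            k += 1
        k = 0
        while k < max_step and _nc_logpost(j, mu[j], R, raw, thetas, choice, reward,
                                           prev, offsets, mu_prior_sd, sig_prior_sd) > ly:
            R += w
            k += 1
        while True:
            x1 = np.random.uniform(L, R)
            if _nc_logpost(j, mu[j], x1, raw, thetas, choice, reward, prev, offsets,
                           mu_prior_sd, sig_prior_sd) >= ly:
                sigma[j] = np.exp(x1)
                break
            if x1 < x0:
                L = x1
            else:
                R = x1
        for s in range(S):
            thetas[s, j] = mu[j] + sigma[j] * raw[s]


@njit(cache=False)
def update_subjects_slice(thetas, mu, sigma, choice, reward, prev, offsets, w, max_step):
    """One Gibbs sweep over all subject coordinates using stepping-out slice
    sampling (Neal 2003). Mutates ``thetas`` in place."""
    S = thetas.shape[0]
    theta_s = np.empty(3)
    for s in range(S):
        a, b = offsets[s], offsets[s + 1]
        ch = choice[a:b]
        rw = reward[a:b]
        pv = prev[a:b]
        for j in range(3):
            for k in range(3):
                theta_s[k] = thetas[s, k]
            x0 = theta_s[j]
            ly = _subject_logpost(theta_s, ch, rw, pv, mu, sigma) \
                - np.random.exponential(1.0)
            # step out
            u = np.random.uniform(0.0, 1.0)
            L = x0 - w * u
            R = L + w
            jj = 0
            theta_s[j] = L
            while jj < max_step and _subject_logpost(theta_s, ch, rw, pv, mu, sigma) > ly:
                L -= w
                theta_s[j] = L
                jj += 1
            jj = 0
            theta_s[j] = R
            while jj < max_step and _subject_logpost(theta_s, ch, rw, pv, mu, sigma) > ly:
                R += w
                theta_s[j] = R
                jj += 1
            # shrink
            while True:
                x1 = np.random.uniform(L, R)
                theta_s[j] = x1
                if _subject_logpost(theta_s, ch, rw, pv, mu, sigma) >= ly:
                    thetas[s, j] = x1
                    break
                if x1 < x0:
                    L = x1
                else:
                    R = x1
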