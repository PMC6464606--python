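"""Statistical engines: per-timepoint mixed-effects regression with BH
correction, and multi-event kernel regression with cluster-robust covariance.

The pointwise engine fits, independently at each of the 45 epoch timepoints,

    z ~ intercept + choice + value + choice:value [+ log_latency]

with random effects grouped by recording site (random intercept plus, by
default, random slopes for choice and value, falling back to intercepts-only
when the fuller model fails). ``value`` is the per-site standardized Q-value
difference in a declared reference frame (chosen-vs-unchosen or
contra-vs-ipsi); the frame is carried in the result metadata because the
interaction's behavior across frames is what discriminates the generative
hypotheses. P-values are Wald z (large-sample normal) and are BH-corrected
across the 45 timepoints separately per regressor.

The kernel engine regresses the continuous z-scored trace on lagged
indicator kernels (-1 s .. +2 s, 45 lags) for three events (nose poke, lever
presentation, lever press) x four conditions (contra/ipsi choice x previous
trial rewarded or not), with sandwich (cluster-robust) standard errors
grouped by site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .behavior import CONTRA, IPSI, NONE
from .photometry import PhotometryTrace
from .preprocess import EPOCH_POST, EPOCH_PRE, EpochMatrix, event_sample_indices

__all__ = [
    "PointwiseDesign",
    "RegressionResult",
    "KernelFit",
    "build_pointwise_design",
    "pointwise_mixed_regression",
    "bh_adjust",
    "significance_tier",
    "kernel_regression",
    "cluster_robust_cov",
]

KERNEL_EVENTS = ("nose_poke", "lever_present", "lever_press")
KERNEL_CONDITIONS = (
    (CONTRA, 1.0), (CONTRA, 0.0), (IPSI, 1.0), (IPSI, 0.0),
)


@dataclass
class PointwiseDesign:
    """Trial-level design for the pointwise regression.

    ``choice`` coded contra = 1 / ipsi = 0 (the intercept is the ipsi mean);
    ``value`` is the standardized Q-value difference in ``frame``.
    """

    choice: np.ndarray
    value: np.ndarray
    site: np.ndarray
    frame: str
    log_latency: np.ndarray | None = None

    def matrix(self) -> tuple[np.ndarray, list]:
        cols = [np.ones_like(self.value), self.choice, self.value,
                self.choice * self.value]
        names = ["intercept", "choice", "value", "interaction"]
        if self.log_latency is not None:
            cols.append(self.log_latency)
            names.append("log_latency")
        return np.column_stack(cols), names


@dataclass
class RegressionResult:
    """Long-format per-timepoint fixed effects with raw and BH-adjusted p."""

    table: pd.DataFrame  # columns: timepoint, time_s, term, coef, se, p, p_adj, tier
    frame: str
    alignment_event: str
    n_sites: int
    n_trials: int
    notes: list = field(default_factory=list)

    def term(self, name: str) -> pd.DataFrame:
        return self.table.loc[self.table["term"] == name].reset_index(drop=True)


def build_pointwise_design(
    trials: pd.DataFrame,
    qtraj: pd.DataFrame,
    epochs: EpochMatrix,
    frame: str = "chosen",
    include_latency: bool = False,
    choice_coding: str = "dummy",
) -> PointwiseDesign:
    """Assemble the design rows matching ``epochs.trial_index_map``.

    ``choice_coding``: "dummy" (contra = 1 / ipsi = 0, intercept = ipsi
    mean) or "effect" (contra = +0.5 / ipsi = -0.5, intercept = grand mean).
    """
    if frame not in ("chosen", "contra"):
        raise ValueError("frame must be 'chosen' or 'contra'")
    if choice_coding not in ("dummy", "effect"):
        raise ValueError("choice_coding must be 'dummy' or 'effect'")
    idx = epochs.trial_index_map
    sub = trials.loc[idx]
    col = "dq_chosen_std" if frame == "chosen" else "dq_contra_std"
    lat = None
    if include_latency:
        lat = np.log(sub["press_latency"].to_numpy(dtype=float))
    choice = (sub["choice"] == CONTRA).to_numpy(dtype=float)
    if choice_coding == "effect":
        choice = choice - 0.5
    return PointwiseDesign(
        choice=choice,
        value=qtraj.loc[idx, col].to_numpy(dtype=float),
        site=sub["site_id"].to_numpy(),
        frame=frame,
        log_latency=lat,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(p_adj: float) -> str:
    if p_adj < 0.001:
        return "0.001"
    if p_adj < 0.01:
        return "0.01"
    if p_adj < 0.05:
        return "0.05"
    return "ns"


def _fit_one_timepoint(y, X, names, groups, random_effects):
    """Mixed model at one timepoint; returns (coefs, ses, pvals, note)."""
    note = ""
    if random_effects == "slopes":
        exog_re = X[:, :3]  # intercept, choice, value
    else:
        exog_re = X[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                reml=True, method="lbfgs", maxiter=200)
            k = X.shape[1]
            # the intercept SE may be NaN when the between-site intercept
            # variance is estimated at zero (expected for per-site z-scored
            # data); only the slope terms must be estimable
            if not np.all(np.isfinite(res.bse[1:k])):
                raise ValueError("non-finite standard errors")
        except Exception:
            if random_effects == "slopes":
                note = "fell back to random intercepts"
                res = MixedLM(y, X, groups=groups, exog_re=X[:, :1]).fit(
                    reml=True, method="lbfgs", maxiter=200)
            else:
                raise
    k = X.shape[1]
    return (np.asarray(res.params[:k]), np.asarray(res.bse[:k]),
            np.asarray(res.pvalues[:k]), note)


def pointwise_mixed_regression(
    epochs: EpochMatrix,
    design: PointwiseDesign,
    random_effects: str = "slopes",
    alpha_tiers_on: str = "adjusted",
) -> RegressionResult:
    """Fit the mixed model independently at each epoch timepoint and
    BH-correct each regressor's p-values across timepoints."""
    sites = np.unique(design.site)
    if len(sites) < 2:
        raise ValueError("pointwise mixed regression needs >= 2 sites")
    if len(design.choice) != epochs.n_trials:
        raise ValueError("design rows do not align with epoch trials")
    X, names = design.matrix()
    rows = []
    notes = []
    for k in range(epochs.values.shape[1]):
        y = epochs.values[:, k]
        try:
            coefs, ses, ps, note = _fit_one_timepoint(
                y, X, names, design.site, random_effects)
        except Exception as exc:  # singular even after fallback: recorded, not fatal
            notes.append(f"timepoint {k}: fit failed ({exc})")
            coefs = np.full(len(names), np.nan)
            ses = np.full(len(names), np.nan)
            ps = np.full(len(names), np.nan)
            note = "failed"
        if note and note != "failed":
            notes.append(f"timepoint {k}: {note}")
        for j, term in enumerate(names):
            rows.append(dict(timepoint=k, time_s=epochs.time_axis[k], term=term,
                             coef=coefs[j], se=ses[j], p=ps[j]))
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for term in table["term"].unique():
        mask = table["term"] == term
        p = table.loc[mask, "p"].to_numpy()
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(p[ok])
        table.loc[mask, "p_adj"] = adj
    basis = "p_adj" if alpha_tiers_on == "adjusted" else "p"
    table["tier"] = [significance_tier(v) if np.isfinite(v) else "ns"
                     for v in table[basis]]
    return RegressionResult(
        table=table, frame=design.frame, alignment_event=epochs.alignment_event,
        n_sites=len(sites), n_trials=epochs.n_trials, notes=notes,
    )


# ---------------------------------------------------------------------------
# multi-event kernel regression


@dataclass
class KernelFit:
    """Kernel coefficients (event x condition x 45 lags) with cluster-robust SEs."""

    table: pd.DataFrame  # event, condition, lag, lag_s, coef, se
    intercept: float
    intercept_se: float
    cov: np.ndarray
    column_names: list
    n_samples: int
    n_clusters: int


def _condition_index(choice: str, prev_reward: float) -> int | None:
    for i, (c, r) in enumerate(KERNEL_CONDITIONS):
        if choice == c and prev_reward == r:
            return i
    return None


def build_kernel_design(
    traces: dict[str, PhotometryTrace],
    z_by_site: dict[str, np.ndarray],
    trials: pd.DataFrame,
    lags: tuple[int, int] = (-EPOCH_PRE, EPOCH_POST),
):
    """Sparse lagged-indicator design over the concatenated z traces.

    Columns: 3 events x 4 conditions x n_lags, plus a global intercept
    (last column). Returns (X sparse, y, clusters, column names).
    """
    lo, hi = lags
    n_lags = hi - lo
    names = [f"{ev}:{c}:{'prev_rew' if r == 1.0 else 'prev_unrew'}:{l}"
             for ev in KERNEL_EVENTS for (c, r) in KERNEL_CONDITIONS
             for l in range(lo, hi)]
    names.append("intercept")
    n_cols = len(names)

    ys, clusters, blocks = [], [], []
    row_base = 0
    data, ri, ci = [], [], []
    for site_id, trace in traces.items():
        z = z_by_site[site_id]
        site_trials = trials.loc[trials["site_id"] == site_id]
        ev_samples = {ev: event_sample_indices(trace, site_trials, ev)
                      for ev in KERNEL_EVENTS}
        n = len(z)
        for t_idx, row in site_trials.iterrows():
            if row["abandoned"] or row["prev_choice"] == NONE:
                continue
            cond = _condition_index(row["choice"], float(row["prev_reward"]))
            if cond is None:
                continue
            for e_i, ev in enumerate(KERNEL_EVENTS):
                k = int(ev_samples[ev].loc[t_idx])
                if k < 0:
                    continue
                col0 = (e_i * len(KERNEL_CONDITIONS) + cond) * n_lags
                for l in range(lo, hi):
                    r = k + l
                    if 0 <= r < n:
                        data.append(1.0)
                        ri.append(row_base + r)
                        ci.append(col0 + (l - lo))
        ys.append(z)
        clusters.append(np.full(n, site_id, dtype=object))
        row_base += n
    y = np.concatenate(ys)
    # intercept column
    data.extend([1.0] * len(y))
    ri.extend(range(len(y)))
    ci.extend([n_cols - 1] * len(y))
    X = sp.coo_matrix((data, (ri, ci)), shape=(len(y), n_cols)).tocsr()
    X.sum_duplicates()
    return X, y, np.concatenate(clusters), names


def kernel_regression(
    traces: dict[str, PhotometryTrace],
    z_by_site: dict[str, np.ndarray],
    trials: pd.DataFrame,
    lags: tuple[int, int] = (-EPOCH_PRE, EPOCH_POST),
) -> KernelFit:
    """Least-squares kernel fit over the continuous traces with
    cluster-robust (CR1 sandwich) covariance grouped by site."""
    X, y, clusters, names = build_kernel_design(traces, z_by_site, trials, lags)
    XtX = np.asarray((X.T @ X).todense())
    Xty = np.asarray(X.T @ y).ravel()
    # drop all-zero columns (conditions that never occur) from the solve
    active = np.flatnonzero(np.diag(XtX) > 0)
    sub = XtX[np.ix_(active, active)]
    rank = np.linalg.matrix_rank(sub)
    if rank < len(active):
        # pivoted QR: the trailing pivots are the linearly dependent columns
        from scipy.linalg import qr
        _, _, piv = qr(sub, pivoting=True)
        dependent = [names[active[i]] for i in piv[rank:rank + 20]]
        raise np.linalg.LinAlgError(
            f"kernel design is rank-deficient (rank {rank} of {len(active)}); "
            f"dependent columns include: {dependent}")
    beta = np.zeros(X.shape[1])
    beta[active] = np.linalg.solve(sub, Xty[active])
    resid = y - X @ beta
    if len(np.unique(clusters)) >= 2:
        cov_act = cluster_robust_cov(X[:, active], resid, clusters)
    else:
        s2 = float(resid @ resid) / (len(y) - len(active))
        cov_act = s2 * np.linalg.inv(sub)
    cov = np.zeros((X.shape[1], X.shape[1]))
    cov[np.ix_(active, active)] = cov_act
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    lo, hi = lags
    n_lags = hi - lo
    rows = []
    i = 0
    for ev in KERNEL_EVENTS:
        for (c, r) in KERNEL_CONDITIONS:
            cond = f"{c}:{'prev_rew' if r == 1.0 else 'prev_unrew'}"
            for l in range(lo, hi):
                rows.append(dict(event=ev, condition=cond, lag=l,
                                 lag_s=l / 15.0, coef=beta[i], se=se[i]))
                i += 1
    table = pd.DataFrame(rows)
    return KernelFit(table=table, intercept=float(beta[-1]),
                     intercept_se=float(se[-1]), cov=cov, column_names=names,
                     n_samples=len(y), n_clusters=len(np.unique(clusters)))


def cluster_robust_cov(X, resid: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """CR1 sandwich covariance of OLS coefficients.

    bread = (X'X)^-1; meat = sum over clusters g of (X_g' e_g)(X_g' e_g)';
    scaled by the CR1 small-sample factor G/(G-1) * (N-1)/(N-K). Symmetric
    PSD by construction.
    """
    labels = np.unique(clusters)
    if len(labels) < 2:
        raise ValueError("cluster-robust covariance needs >= 2 clusters")
    issparse = sp.issparse(X)
    XtX = np.asarray((X.T @ X).todense()) if issparse else X.T @ X
    bread = np.linalg.inv(XtX)
    K = XtX.shape[0]
    N = X.shape[0]
    G = len(labels)
    meat = np.zeros((K, K))
    for g in labels:
        m = clusters == g
        Xg = X[m]
        s = np.asarray(Xg.T @ resid[m]).ravel()
        meat += np.outer(s, s)
    c = (G / (G - 1)) * ((N - 1) / (N - K))
    cov = c * bread @ meat @ bread
    return 0.5 * (cov + cov.T)
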