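"""End-to-end orchestration: simulate (or ingest) -> fit -> preprocess ->
regress -> bin -> discriminate which generative hypothesis produced the data.

The discrimination logic is the scientific core: a value signal tied to the
*contralateral* action produces, when analyzed in the chosen-value frame, a
sign flip of the value modulation between contra and ipsi choices — i.e. a
sustained choice-by-value interaction — and no interaction in the
contra-value frame; a *chosen*-value signal produces the mirror-image
pattern. A significant choice main effect on top of a chosen-value pattern
indicates an additional movement-direction component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .behavior import (CONTRA, IPSI, NONE, AgentParams, TaskConfig,
                       reversal_aligned_choice_curve, simulate_cohort,
                       stay_fraction)
from .photometry import PhotometryConfig, PhotometryTrace, synthesize_trace
from .preprocess import (EpochMatrix, FilterSpec, event_sample_indices,
                         extract_epochs, preprocess_trace)
from .qfit import FitConfig, FitResult, compute_q_trajectories, fit_hierarchical
from .regression import (RegressionResult, build_pointwise_design,
                         kernel_regression, pointwise_mixed_regression)

__all__ = [
    "GROUP_MEDIANS",
    "GROUP_SIGMAS",
    "sample_cohort_params",
    "BinnedTraces",
    "DiscriminationReport",
    "bin_by_prev_outcome",
    "bin_by_dq",
    "difference_crossing",
    "press_locked_crossing",
    "discriminate_frame",
    "PipelineConfig",
    "run_full_pipeline",
]

# Group-median Q-learning parameters fitted to mice on this reversal task
# (learning rate, inverse temperature, stay bonus), and the implied
# subject-level spread on the unconstrained scales (IQR / 1.349 from the
# fitted 25th/75th percentiles). These are the default study conditions for
# every synthetic cohort.
GROUP_MEDIANS = AgentParams(alpha=0.611693, beta=0.990275, stay=0.945385)
GROUP_SIGMAS = {
    "logit_alpha": (np.log(0.639946 / (1 - 0.639946)) - np.log(0.581607 / (1 - 0.581607))) / 1.3489795,
    "log_beta": (np.log(1.058405) - np.log(0.926501)) / 1.3489795,
    "stay": (1.008465 - 0.883670) / 1.3489795,
}


def sample_cohort_params(n_subjects: int, seed: int = 0) -> list[AgentParams]:
    """Draw per-subject parameters from the default group-level distribution
    (Gaussian on the unconstrained scales, centered at the group medians)."""
    rng = np.random.default_rng(seed)
    mu = np.array([
        np.log(GROUP_MEDIANS.alpha / (1 - GROUP_MEDIANS.alpha)),
        np.log(GROUP_MEDIANS.beta),
        GROUP_MEDIANS.stay,
    ])
    sd = np.array([GROUP_SIGMAS["logit_alpha"], GROUP_SIGMAS["log_beta"],
                   GROUP_SIGMAS["stay"]])
    out = []
    for _ in range(n_subjects):
        x = mu + sd * rng.standard_normal(3)
        out.append(AgentParams(alpha=float(expit(x[0])),
                               beta=float(np.exp(x[1])), stay=float(x[2])))
    return out


# ---------------------------------------------------------------------------
# binned condition averages


@dataclass
class BinnedTraces:
    """Condition-averaged event-locked traces (mean across sites, SE)."""

    labels: list
    mean: np.ndarray        # n_conditions x 45
    se: np.ndarray
    n_trials: dict
    time_axis: np.ndarray
    metadata: dict = field(default_factory=dict)


def _site_condition_means(epochs: EpochMatrix, groups: pd.Series, sites: pd.Series):
    """Mean trace per (site, condition); then mean and SE across sites."""
    labels = sorted(groups.dropna().unique())
    per_site = {}
    counts = {lab: 0 for lab in labels}
    for lab in labels:
        sel = groups == lab
        counts[lab] = int(sel.sum())
        by_site = []
        for s in sites.unique():
            m = sel & (sites == s)
            if m.any():
                by_site.append(epochs.values[m.to_numpy()].mean(axis=0))
        per_site[lab] = np.vstack(by_site) if by_site else None
    mean = np.full((len(labels), epochs.values.shape[1]), np.nan)
    se = np.full_like(mean, np.nan)
    for i, lab in enumerate(labels):
        mat = per_site[lab]
        if mat is None:
            continue
        mean[i] = mat.mean(axis=0)
        if mat.shape[0] > 1:
            se[i] = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return labels, mean, se, counts


def bin_by_prev_outcome(epochs: EpochMatrix, trials: pd.DataFrame) -> BinnedTraces:
    """Stay trials only: condition means for contra/ipsi choice x previous
    trial rewarded or not. Missing conditions stay as NaN rows, not errors."""
    sub = trials.loc[epochs.trial_index_map]
    stay = ((sub["choice"] == sub["prev_choice"])
            & (sub["prev_choice"] != NONE)
            & (~sub["abandoned"].astype(bool)))
    groups = pd.Series(np.nan, index=sub.index, dtype=object)
    for side in (CONTRA, IPSI):
        for rew, tag in ((1.0, "prev_rew"), (0.0, "prev_unrew")):
            m = stay & (sub["choice"] == side) & (sub["prev_reward"] == rew)
            groups[m] = f"{side}:{tag}"
    labels, mean, se, counts = _site_condition_means(epochs, groups, sub["site_id"])
    return BinnedTraces(labels=labels, mean=mean, se=se, n_trials=counts,
                        time_axis=epochs.time_axis,
                        metadata={"filter": "stay trials only"})


def quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign values to quantile bins 0..n_bins-1 (right-closed edges)."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="left")


def bin_by_dq(
    epochs: EpochMatrix,
    trials: pd.DataFrame,
    qtraj: pd.DataFrame,
    n_bins: int = 3,
    frame: str = "chosen",
) -> BinnedTraces:
    """Condition means for choice x Q-value-difference bin (stay and switch
    trials alike). Bin edges are within-site quantiles of the standardized
    value difference in the requested frame."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sub = trials.loc[epochs.trial_index_map]
    col = "dq_chosen_std" if frame == "chosen" else "dq_contra_std"
    vals = qtraj.loc[sub.index, col]
    groups = pd.Series(np.nan, index=sub.index, dtype=object)
    for s in sub["site_id"].unique():
        m = (sub["site_id"] == s) & (~sub["abandoned"].astype(bool))
        if not m.any():
            continue
        bins = quantile_bins(vals[m].to_numpy(), n_bins)
        for (idx, side), b in zip(sub.loc[m, "choice"].items(), bins):
            groups[idx] = f"{side}:dq_bin{b}"
    labels, mean, se, counts = _site_condition_means(epochs, groups, sub["site_id"])
    return BinnedTraces(labels=labels, mean=mean, se=se, n_trials=counts,
                        time_axis=epochs.time_axis,
                        metadata={"n_bins": n_bins, "frame": frame})


def difference_crossing(
    epochs: EpochMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    sites: np.ndarray,
    min_sustained: int = 3,
    min_frac: float = 0.5,
) -> float | None:
    """First post-event zero crossing of the (A minus B) condition-difference
    trace; None if the difference never reverses.

    A reversal requires substantial sustained excursions of *both* signs:
    runs of >= ``min_sustained`` samples exceeding ``min_frac`` of the
    trace's peak |difference|, with the opposite-sign run beginning at or
    after the alignment event and after a run of the initial sign. This
    rejects the shallow opposite-sign rebound that zero-mean
    (high-pass-filtered) traces always develop around dense transients.
    """
    diff_by_site = []
    for s in np.unique(sites):
        ma = mask_a & (sites == s)
        mb = mask_b & (sites == s)
        if ma.any() and mb.any():
            diff_by_site.append(epochs.values[ma].mean(axis=0)
                                - epochs.values[mb].mean(axis=0))
    if not diff_by_site:
        return None
    diff = np.vstack(diff_by_site).mean(axis=0)
    t = epochs.time_axis
    threshold = min_frac * np.abs(diff).max()
    if threshold == 0:
        return None

    def runs(sign):
        out = []
        start = None
        for i, v in enumerate(sign * diff > threshold):
            if v and start is None:
                start = i
            elif not v and start is not None:
                if i - start >= min_sustained:
                    out.append((start, i))
                start = None
        if start is not None and len(diff) - start >= min_sustained:
            out.append((start, len(diff)))
        return out

    pos, neg = runs(+1.0), runs(-1.0)
    if not pos or not neg:
        return None
    first_sign = +1.0 if pos[0][0] <= neg[0][0] else -1.0
    lead_end = pos[0][1] if first_sign > 0 else neg[0][1]
    for start, _ in (neg if first_sign > 0 else pos):
        if start >= lead_end and t[start] >= 0:
            return float(t[start])
    return None


def press_locked_crossing(
    epochs: EpochMatrix,
    trials: pd.DataFrame,
    min_sustained: int = 3,
) -> float | None:
    """Zero crossing of the contra-minus-ipsi selectivity after the aligned
    event (the movement-direction reversal signature); None if the
    selectivity keeps its pre-event sign."""
    sub = trials.loc[epochs.trial_index_map]
    return difference_crossing(
        epochs,
        (sub["choice"] == CONTRA).to_numpy(),
        (sub["choice"] == IPSI).to_numpy(),
        sub["site_id"].to_numpy(),
        min_sustained=min_sustained,
    )


# ---------------------------------------------------------------------------
# hypothesis discrimination


@dataclass
class DiscriminationReport:
    inferred_hypothesis: str
    evidence: dict
    true_hypothesis: str | None = None
    replicate: int | None = None
    seed: int | None = None

    @property
    def correct(self) -> bool | None:
        if self.true_hypothesis is None:
            return None
        return self.inferred_hypothesis == self.true_hypothesis


def _sustained(sig: np.ndarray, run: int) -> bool:
    best = cur = 0
    for s in sig:
        cur = cur + 1 if s else 0
        best = max(best, cur)
    return best >= run


def _window_significance(result: RegressionResult, term: str,
                         window: tuple[float, float], alpha: float,
                         run: int) -> bool:
    tab = result.term(term)
    m = (tab["time_s"] >= window[0]) & (tab["time_s"] <= window[1])
    sig = (tab.loc[m, "p_adj"] < alpha).to_numpy()
    return _sustained(sig, run)


def discriminate_frame(
    trials: pd.DataFrame,
    results_chosen: RegressionResult,
    results_contra: RegressionResult,
    window: tuple[float, float] = (0.25, 1.0),
    alpha: float = 0.05,
    sustained_run: int = 4,
    true_hypothesis: str | None = None,
    seed: int | None = None,
) -> DiscriminationReport:
    """Label the generative hypothesis from the interaction pattern across
    the two value reference frames.

    A sustained interaction (>= ``sustained_run`` consecutive BH-significant
    timepoints within ``window``) in the chosen frame but not the contra
    frame implies contralateral-value coding; the mirror pattern implies
    chosen-value coding, with vs without an additional movement component
    according to the choice main effect.
    """
    try:
        chosen_ix = _window_significance(results_chosen, "interaction", window,
                                         alpha, sustained_run)
        contra_ix = _window_significance(results_contra, "interaction", window,
                                         alpha, sustained_run)
        choice_me = _window_significance(results_chosen, "choice", window,
                                         alpha, sustained_run)
        value_me = _window_significance(results_chosen, "value", window,
                                        alpha, sustained_run)
    except Exception as exc:
        return DiscriminationReport(
            inferred_hypothesis="indeterminate",
            evidence={"error": str(exc)},
            true_hypothesis=true_hypothesis, seed=seed)

    if chosen_ix and not contra_ix:
        label = "contra_value"
    elif contra_ix and not chosen_ix and choice_me:
        label = "chosen_value_plus_movement"
    elif contra_ix and not chosen_ix:
        label = "chosen_value"
    else:
        label = "indeterminate"
    evidence = {
        "interaction_sustained_chosen_frame": bool(chosen_ix),
        "interaction_sustained_contra_frame": bool(contra_ix),
        "choice_main_effect": bool(choice_me),
        "value_main_effect": bool(value_me),
        "window_s": list(window),
        "alpha": alpha,
        "sustained_run": sustained_run,
    }
    return DiscriminationReport(inferred_hypothesis=label, evidence=evidence,
                                true_hypothesis=true_hypothesis, seed=seed)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """Settings for one synthetic end-to-end run."""

    n_sites: int = 6
    task: TaskConfig = field(default_factory=lambda: TaskConfig(
        trials_per_session=150, sessions_per_site=2))
    photometry: PhotometryConfig = field(default_factory=PhotometryConfig)
    fit_method: str = "per_subject_mle"
    random_effects: str = "intercept"
    alignments: tuple = ("nose_poke", "lever_present", "lever_press")
    run_kernel_regression: bool = True
    n_dq_bins: int = 3
    seed: int = 0


def _fit_cohort(trials: pd.DataFrame, method: str, seed: int) -> FitResult:
    cfg = FitConfig(method=method, rng_seed=seed,
                    n_chains=4 if method == "hierarchical_mcmc" else 1,
                    keep_samples=False)
    return fit_hierarchical(trials, cfg)


def run_full_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate a cohort under the configured hypothesis, run the complete
    analysis, and (optionally) write a report directory.

    Deterministic given ``config.seed``. Returns a bundle with the trial
    table, fitted parameters, per-alignment regression results in both
    frames, binned traces, kernel fit, press-locked crossing, and the
    hypothesis-discrimination report.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    subject_params = sample_cohort_params(
        config.n_sites, seed=int(seeds[0].generate_state(1)[0] % 2**31))
    task = config.task
    trials = simulate_cohort(subject_params, task,
                             seed=int(seeds[1].generate_state(1)[0] % 2**31))

    fit = _fit_cohort(trials, config.fit_method, config.seed)
    qtraj = compute_q_trajectories(fit.subject_params, trials)

    # generative Q trajectories drive the synthetic photometry
    true_params = {f"site{i}": p for i, p in enumerate(subject_params)}
    qtraj_true = compute_q_trajectories(true_params, trials)

    phot_children = np.random.SeedSequence(
        int(seeds[2].generate_state(1)[0] % 2**31)).spawn(config.n_sites)
    traces, z_by_site = {}, {}
    spec = FilterSpec(sampling_rate=config.photometry.sampling_rate)
    for child, (site_id, df) in zip(phot_children,
                                    trials.groupby("site_id", sort=False)):
        rng = np.random.default_rng(child)
        tr = synthesize_trace(df, qtraj_true.loc[df.index], config.photometry, rng)
        traces[site_id] = tr
        z_by_site[site_id] = preprocess_trace(tr, spec)

    regressions = {}
    epochs_by_alignment = {}
    for alignment in config.alignments:
        ep = _cohort_epochs(traces, z_by_site, trials, alignment)
        epochs_by_alignment[alignment] = ep
        for frame in ("chosen", "contra"):
            design = build_pointwise_design(trials, qtraj, ep, frame=frame)
            regressions[(alignment, frame)] = pointwise_mixed_regression(
                ep, design, random_effects=config.random_effects)

    ep_present = epochs_by_alignment.get("lever_present")
    binned_prev = bin_by_prev_outcome(ep_present, trials) if ep_present is not None else None
    binned_dq = (bin_by_dq(ep_present, trials, qtraj, n_bins=config.n_dq_bins)
                 if ep_present is not None else None)
    ep_press = epochs_by_alignment.get("lever_press")
    crossing = press_locked_crossing(ep_press, trials) if ep_press is not None else None

    kernels = None
    if config.run_kernel_regression:
        kernels = kernel_regression(traces, z_by_site, trials)

    report = discriminate_frame(
        trials,
        regressions[("lever_present", "chosen")],
        regressions[("lever_present", "contra")],
        true_hypothesis=config.photometry.hypothesis,
        seed=config.seed,
    )

    bundle = {
        "config": config,
        "trials": trials,
        "fit": fit,
        "qtraj": qtraj,
        "choice_curve": reversal_aligned_choice_curve(trials),
        "stay_fraction": stay_fraction(trials),
        "regressions": regressions,
        "binned_prev_outcome": binned_prev,
        "binned_dq": binned_dq,
        "press_crossing": crossing,
        "kernels": kernels,
        "discrimination": report,
    }
    if out_dir is not None:
        _write_report(bundle, Path(out_dir))
    return bundle


def _cohort_epochs(traces, z_by_site, trials, alignment) -> EpochMatrix:
    """Epochs for all sites on a shared 45-sample grid."""
    mats, labels = [], []
    dropped = []
    time_axis = None
    for site_id, trace in traces.items():
        df = trials.loc[trials["site_id"] == site_id]
        ks = event_sample_indices(trace, df, alignment)
        ep = extract_epochs(z_by_site[site_id], ks, alignment,
                            trace.sampling_rate, trace.session_offsets)
        mats.append(ep.values)
        labels.append(ep.trial_index_map)
        dropped.extend(ep.dropped)
        time_axis = ep.time_axis
    return EpochMatrix(values=np.vstack(mats), time_axis=time_axis,
                       alignment_event=alignment,
                       trial_index_map=np.concatenate(labels), dropped=dropped)


def _write_report(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["trials"].to_csv(out / "trials.csv", index=False)
    bundle["qtraj"].to_csv(out / "qtraj.csv", index=False)
    bundle["choice_curve"].to_csv(out / "choice_curve.csv", index=False)
    for (alignment, frame), res in bundle["regressions"].items():
        res.table.to_csv(out / f"regression_{alignment}_{frame}.csv", index=False)
    if bundle["kernels"] is not None:
        bundle["kernels"].table.to_csv(out / "kernels.csv", index=False)
    fit = bundle["fit"]
    summary = {
        "stay_fraction": bundle["stay_fraction"],
        "press_crossing_s": bundle["press_crossing"],
        "discrimination": asdict(bundle["discrimination"]),
        "group_percentiles": fit.group_percentiles.to_dict(),
        "rhat_max": fit.max_rhat() if fit.rhat else None,
        "subject_params": {k: asdict(v) for k, v in fit.subject_params.items()},
        "config": {
            "n_sites": bundle["config"].n_sites,
            "seed": bundle["config"].seed,
            "hypothesis": bundle["config"].photometry.hypothesis,
            "task": bundle["config"].task.to_dict(),
            "photometry": bundle["config"].photometry.to_dict(),
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    _write_figures(bundle, out)


def _write_figures(bundle: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    cc = bundle["choice_curve"]
    ax.errorbar(cc["lag"], cc["p_pre_high"], yerr=cc["se"], color="k")
    ax.axvline(0, ls="--", c="grey")
    ax.set(xlabel="trials from block switch", ylabel="P(pre-switch high lever)")
    fig.tight_layout()
    fig.savefig(out / "choice_curve.png", dpi=120)
    plt.close(fig)

    if bundle["binned_prev_outcome"] is not None:
        bt = bundle["binned_prev_outcome"]
        fig, ax = plt.subplots(figsize=(4, 3))
        for lab, m in zip(bt.labels, bt.mean):
            style = "-" if "prev_rew" in lab else ":"
            color = "tab:blue" if lab.startswith("contra") else "tab:orange"
            ax.plot(bt.time_axis, m, style, color=color, label=lab)
        ax.axvline(0, ls="--", c="grey")
        ax.set(xlabel="time from lever presentation (s)", ylabel="z dF/F")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "binned_prev_outcome.png", dpi=120)
        plt.close(fig)

    res = bundle["regressions"].get(("lever_present", "chosen"))
    if res is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        for term, color in (("choice", "tab:blue"), ("value", "tab:orange"),
                            ("interaction", "tab:green")):
            tab = res.term(term)
            ax.plot(tab["time_s"], tab["coef"], color=color, label=term)
            sig = tab["p_adj"] < 0.05
            ax.plot(tab.loc[sig, "time_s"], np.full(sig.sum(), ax.get_ylim()[0]),
                    ".", color=color, ms=3)
        ax.axhline(0, c="grey", lw=0.5)
        ax.set(xlabel="time from lever presentation (s)", ylabel="coefficient")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "pointwise_regression_chosen.png", dpi=120)
        plt.close(fig)
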