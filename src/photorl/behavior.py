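"""Probabilistic reversal-learning task and Q-learning agent simulation.

The task: a mouse initiates a trial at a central nose port; after a short
jittered delay two levers appear, one rewarded with high probability (0.70)
and the other with low probability (0.10). The identity of the high lever
swaps in blocks of at least ``min_rewarded_per_block`` rewarded trials plus a
Geometric(``block_extension_p``) number of extra trials. The agent is a
two-action Q-learner with a softmax policy and a choice-repetition ("stay")
bonus:

    Q_{t+1}(c_t) = Q_t(c_t) + alpha * (r_t - Q_t(c_t))
    P(c_t = c) ∝ exp(beta * Q_t(c) + stay * I(c, c_{t-1}))

Everything is expressed natively in the contra/ipsi frame of a nominal
recording hemisphere. Trial tables are tidy pandas DataFrames with one row
per trial (columns listed in :data:`TRIAL_COLUMNS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "AgentParams",
    "SessionRecord",
    "TRIAL_COLUMNS",
    "draw_block_extension",
    "q_update",
    "choice_prob",
    "simulate_session",
    "simulate_site",
    "simulate_cohort",
    "reversal_aligned_choice_curve",
    "stay_fraction",
    "lever_to_frame",
    "validate_trials",
]

CONTRA = "contra"
IPSI = "ipsi"
NONE = "none"

#: Column schema of a tidy trial table (one row per trial).
TRIAL_COLUMNS = [
    "site_id",
    "session_id",
    "trial_index",
    "block_id",
    "high_side",
    "choice",
    "reward",
    "prev_choice",
    "prev_reward",
    "t_nose_poke",
    "t_lever_present",
    "t_lever_press",
    "t_outcome",
    "press_latency",
    "abandoned",
]


@dataclass
class TaskConfig:
    """Parameters of the reversal task and of the session event clock.

    Delays are in seconds. Jittered delays are drawn uniformly from the grid
    ``{event_jitter_step, 2*step, ..., event_jitter_max}``; the grid starts
    one step above zero so that consecutive event timestamps are strictly
    ordered.
    """

    p_high: float = 0.70
    p_low: float = 0.10
    min_rewarded_per_block: int = 10
    block_extension_p: float = 0.4
    sampling_rate: float = 15.0
    press_deadline: float = 10.0
    event_jitter_max: float = 1.0
    event_jitter_step: float = 0.1
    inter_trial_delay: float = 3.0
    trials_per_session: int = 250
    sessions_per_site: int = 4
    press_latency_median: float = 0.5
    press_latency_sigma: float = 0.5
    reset_q_per_session: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low < self.p_high < 1.0):
            raise ValueError("require 0 < p_low < p_high < 1")
        if not (0.0 < self.block_extension_p < 1.0):
            raise ValueError("block_extension_p must lie in (0, 1)")
        if self.min_rewarded_per_block < 1:
            raise ValueError("min_rewarded_per_block must be >= 1")
        if self.trials_per_session <= 0:
            raise ValueError("trials_per_session must be positive")
        if self.event_jitter_step <= 0 or self.event_jitter_max < self.event_jitter_step:
            raise ValueError("invalid jitter grid")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgentParams:
    """Q-learning parameters for one subject.

    alpha
        learning rate, constrained to [0, 1].
    beta
        softmax inverse temperature, >= 0.
    stay
        additive softmax bonus for repeating the previous choice
        (perseveration when positive, alternation when negative).
    """

    alpha: float
    beta: float
    stay: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class SessionRecord:
    """One session's trials plus the indices (within session) where new blocks begin."""

    trials: pd.DataFrame
    block_boundaries: list = field(default_factory=list)


def draw_block_extension(rng: np.random.Generator, p: float) -> int:
    """Number of extra trials appended to a block once the rewarded-trial
    quota is met.

    Geometric on support {1, 2, ...} with P(k) = p * (1-p)**(k-1), so the
    mean is 1/p (2.5 at the task's p = 0.4).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"geometric parameter must lie in (0, 1], got {p}")
    return int(rng.geometric(p))


def q_update(q_chosen: float, reward: float, alpha: float) -> float:
    """Delta-rule update of the chosen action's value; the unchosen value is untouched."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return q_chosen + alpha * (reward - q_chosen)


def choice_prob(
    q_contra: float,
    q_ipsi: float,
    prev_choice: str | None,
    params: AgentParams,
) -> float:
    """Softmax probability of choosing the contralateral lever.

    ``prev_choice`` is "contra", "ipsi", or "none"/None for the first trial,
    in which case the stay bonus contributes to neither action. The two
    action probabilities sum to one by construction.
    """
    stay_term = 0.0
    if prev_choice == CONTRA:
        stay_term = params.stay
    elif prev_choice == IPSI:
        stay_term = -params.stay
    elif prev_choice not in (NONE, None):
        raise ValueError(f"unknown prev_choice {prev_choice!r}")
    x = params.beta * (q_contra - q_ipsi) + stay_term
    # logistic with overflow guard
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


class _AgentState:
    """Q values and previous-choice memory carried across sessions of one site."""

    __slots__ = ("q_contra", "q_ipsi", "prev_choice", "prev_reward")

    def __init__(self) -> None:
        self.q_contra = 0.0
        self.q_ipsi = 0.0
        self.prev_choice = NONE
        self.prev_reward = np.nan


def _draw_jitter(rng: np.random.Generator, config: TaskConfig) -> float:
    n = int(round(config.event_jitter_max / config.event_jitter_step))
    return config.event_jitter_step * (1 + rng.integers(0, n))


def simulate_session(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    site_id: str = "site0",
    session_id: str = "s0",
    state: _AgentState | None = None,
    high_side: str | None = None,
    block_id_start: int = 0,
) -> SessionRecord:
    """Simulate one session of the reversal task.

    ``state`` carries Q values and previous-choice memory across sessions of
    the same site; pass None for a fresh agent. Returns a
    :class:`SessionRecord`; the agent state and final block assignment can be
    read back from the returned trials.
    """
    if state is None:
        state = _AgentState()
    if high_side is None:
        high_side = CONTRA if rng.random() < 0.5 else IPSI

    rows = []
    block_boundaries = [0]
    block_id = block_id_start
    rewards_in_block = 0
    extension_left = -1  # -1: quota not yet met
    t = 0.0

    for trial_index in range(config.trials_per_session):
        t_nose_poke = t
        t_lever_present = t_nose_poke + _draw_jitter(rng, config)
        latency = float(
            np.exp(np.log(config.press_latency_median)
                   + config.press_latency_sigma * rng.standard_normal())
        )
        abandoned = latency > config.press_deadline

        if abandoned:
            rows.append(dict(
                site_id=site_id, session_id=session_id, trial_index=trial_index,
                block_id=block_id, high_side=high_side, choice=NONE,
                reward=np.nan, prev_choice=state.prev_choice,
                prev_reward=state.prev_reward, t_nose_poke=t_nose_poke,
                t_lever_present=t_lever_present, t_lever_press=np.nan,
                t_outcome=np.nan, press_latency=np.nan, abandoned=True,
            ))
            t = t_lever_present + config.press_deadline + config.inter_trial_delay
        else:
            p_contra = choice_prob(state.q_contra, state.q_ipsi, state.prev_choice, params)
            choice = CONTRA if rng.random() < p_contra else IPSI
            p_reward = config.p_high if choice == high_side else config.p_low
            reward = float(rng.random() < p_reward)

            t_lever_press = t_lever_present + latency
            t_outcome = t_lever_press + _draw_jitter(rng, config)

            rows.append(dict(
                site_id=site_id, session_id=session_id, trial_index=trial_index,
                block_id=block_id, high_side=high_side, choice=choice,
                reward=reward, prev_choice=state.prev_choice,
                prev_reward=state.prev_reward, t_nose_poke=t_nose_poke,
                t_lever_present=t_lever_present, t_lever_press=t_lever_press,
                t_outcome=t_outcome, press_latency=latency, abandoned=False,
            ))

            if choice == CONTRA:
                state.q_contra = q_update(state.q_contra, reward, params.alpha)
            else:
                state.q_ipsi = q_update(state.q_ipsi, reward, params.alpha)
            state.prev_choice = choice
            state.prev_reward = reward
            rewards_in_block += int(reward)
            t = t_outcome + config.inter_trial_delay

        # Block bookkeeping: once the rewarded quota is met, the block runs
        # for a Geometric(p) number of further trials (all trials count),
        # then the high lever swaps before the next trial.
        if extension_left < 0:
            if rewards_in_block >= config.min_rewarded_per_block:
                extension_left = draw_block_extension(rng, config.block_extension_p)
        else:
            extension_left -= 1
        if extension_left == 0 and trial_index + 1 < config.trials_per_session:
            high_side = IPSI if high_side == CONTRA else CONTRA
            block_id += 1
            rewards_in_block = 0
            extension_left = -1
            block_boundaries.append(trial_index + 1)

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionRecord(trials=trials, block_boundaries=block_boundaries)


def simulate_site(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    site_id: str = "site0",
) -> pd.DataFrame:
    """Simulate ``config.sessions_per_site`` sessions for one recording site.

    Q values and the stay indicator are carried across session boundaries
    (sessions are concatenated for analysis); set
    ``config.reset_q_per_session`` to start each session from Q = 0.
    """
    state = _AgentState()
    frames = []
    block_id_start = 0
    for s in range(config.sessions_per_site):
        if config.reset_q_per_session:
            state.q_contra = 0.0
            state.q_ipsi = 0.0
        rec = simulate_session(
            params, config, rng,
            site_id=site_id, session_id=f"s{s}",
            state=state, block_id_start=block_id_start,
        )
        frames.append(rec.trials)
        block_id_start = int(rec.trials["block_id"].iloc[-1]) + 1
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    subject_params: list[AgentParams] | dict[str, AgentParams],
    config: TaskConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of sites, one agent per site.

    Per-site child seeds are spawned deterministically from the master seed
    (``config.rng_seed`` unless ``seed`` is given), so any site is
    reproducible in isolation.
    """
    if isinstance(subject_params, dict):
        items = list(subject_params.items())
    else:
        items = [(f"site{i}", p) for i, p in enumerate(subject_params)]
    master = np.random.SeedSequence(config.rng_seed if seed is None else seed)
    children = master.spawn(len(items))
    frames = []
    for (site_id, params), child in zip(items, children):
        rng = np.random.default_rng(child)
        frames.append(simulate_site(params, config, rng, site_id=site_id))
    return pd.concat(frames, ignore_index=True)


def stay_fraction(trials: pd.DataFrame) -> float:
    """Fraction of completed, non-first trials on which the choice repeats
    the previous completed trial's choice."""
    ok = (~trials["abandoned"].astype(bool)) & (trials["prev_choice"] != NONE)
    sub = trials.loc[ok]
    if len(sub) == 0:
        raise ValueError("no eligible trials")
    return float((sub["choice"] == sub["prev_choice"]).mean())


def reversal_aligned_choice_curve(
    trials: pd.DataFrame, window: int = 10
) -> pd.DataFrame:
    """Probability of choosing the lever that was high-value *before* each
    block switch, from ``window`` trials before to ``window`` after.

    Returns a DataFrame with columns ``lag`` (-window..window, 0 = first
    trial of the new block), ``p_pre_high`` (mean across sites), ``se``
    (standard error across sites) and ``n_sites``.
    """
    lags = np.arange(-window, window + 1)
    per_site = []
    for _, site_df in trials.groupby("site_id", sort=False):
        site_df = site_df.reset_index(drop=True)
        switches = np.flatnonzero(np.diff(site_df["block_id"].to_numpy()) != 0) + 1
        if len(switches) == 0:
            continue
        acc = np.zeros(len(lags))
        cnt = np.zeros(len(lags))
        choices = site_df["choice"].to_numpy()
        high = site_df["high_side"].to_numpy()
        abandoned = site_df["abandoned"].to_numpy(dtype=bool)
        for s in switches:
            pre_high = high[s - 1]
            for j, lag in enumerate(lags):
                i = s + lag
                if 0 <= i < len(site_df) and not abandoned[i]:
                    acc[j] += choices[i] == pre_high
                    cnt[j] += 1
        with np.errstate(invalid="ignore"):
            per_site.append(acc / cnt)
    if not per_site:
        raise ValueError("no block switches found in the trial table")
    mat = np.vstack(per_site)
    mean = np.nanmean(mat, axis=0)
    n = np.sum(~np.isnan(mat), axis=0)
    se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame({"lag": lags, "p_pre_high": mean, "se": se, "n_sites": n})


def lever_to_frame(lever_side: str, hemisphere: str) -> str:
    """Map a physical lever side ('left'/'right') and recording hemisphere
    ('left'/'right') to the contra/ipsi frame of that hemisphere."""
    sides = {"left", "right"}
    if lever_side not in sides or hemisphere not in sides:
        raise ValueError("lever_side and hemisphere must be 'left' or 'right'")
    return IPSI if lever_side == hemisphere else CONTRA


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table invariants; raise ValueError on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    done = trials.loc[~trials["abandoned"].astype(bool)]
    t = done[["t_nose_poke", "t_lever_present", "t_lever_press", "t_outcome"]].to_numpy()
    if not np.all(np.diff(t, axis=1) > 0):
        raise ValueError("event timestamps not strictly increasing on completed trials")
    lat = done["press_latency"].to_numpy()
    expect = done["t_lever_press"].to_numpy() - done["t_lever_present"].to_numpy()
    if not np.allclose(lat, expect, atol=1e-9):
        raise ValueError("press_latency inconsistent with event timestamps")
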