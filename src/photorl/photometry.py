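"""Synthetic GCaMP6f-like fiber-photometry traces at 15 Hz.

Event-locked transient amplitudes follow one of three competing generative
hypotheses about what modulates the signal at lever presentation:

``contra_value``
    amplitude proportional to Q(contra) - Q(ipsi), regardless of choice
    (an action-specific anticipatory prediction error).
``chosen_value``
    amplitude proportional to Q(chosen) - Q(unchosen) (the classic
    critic-style anticipatory RPE).
``chosen_value_plus_movement``
    chosen-value modulation plus a fixed additive component on
    contralateral-choice trials (movement-direction selectivity).

Traces are generated in raw fluorescence units as
``baseline * (1 + drift + transients + noise)`` so that the downstream
high-pass filter, dF/F and z-scoring stages all do real work. The transient
shape is a unit-peak double-exponential stand-in for a GCaMP6f impulse
response. Under ``movement_reversal`` the movement component is re-expressed
at the lever press with flipped sign, emulating selectivity that follows the
physical movement direction (toward the lever before the press, back toward
the reward port after).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .behavior import CONTRA

__all__ = [
    "HYPOTHESES",
    "PhotometryConfig",
    "PhotometryTrace",
    "calcium_kernel",
    "trial_amplitude",
    "synthesize_trace",
]

HYPOTHESES = ("contra_value", "chosen_value", "chosen_value_plus_movement")


@dataclass
class PhotometryConfig:
    """Generator settings.

    Gains are in fractional-fluorescence (dF/F) units: ``value_gain`` per
    unit of (unstandardized) Q-value difference, ``movement_gain`` as a flat
    increment on contralateral trials. Defaults are calibrated so that
    z-scored event-locked responses come out of order ~1 z-unit, the scale
    seen in striatal dopamine photometry.
    """

    hypothesis: str = "chosen_value_plus_movement"
    value_gain: float = 0.15
    movement_gain: float = 0.08
    movement_reversal: bool = True
    kernel_tau_rise: float = 0.1
    kernel_tau_decay: float = 0.6
    noise_sd: float = 0.05
    drift_amplitude: float = 0.10
    drift_timescale: float = 60.0
    baseline_f: float = 100.0
    sampling_rate: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}; "
                             f"expected one of {HYPOTHESES}")
        if not (self.kernel_tau_decay > self.kernel_tau_rise >= 0.0):
            raise ValueError("require kernel_tau_decay > kernel_tau_rise >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhotometryTrace:
    """Continuous raw-fluorescence recording for one site.

    ``session_offsets`` holds the starting sample index of each session
    (length = number of sessions); ``session_ids`` the matching labels.
    """

    site_id: str
    sampling_rate: float
    samples: np.ndarray
    session_offsets: list = field(default_factory=lambda: [0])
    session_ids: list = field(default_factory=lambda: ["s0"])

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        off = np.asarray(self.session_offsets)
        if np.any(np.diff(off) <= 0) or off[0] != 0 or np.any(off >= len(self.samples)):
            raise ValueError("session_offsets must be strictly increasing, start at 0, "
                             "and lie within the trace")

    def session_bounds(self) -> list[tuple[int, int]]:
        edges = list(self.session_offsets) + [len(self.samples)]
        return list(zip(edges[:-1], edges[1:]))


def calcium_kernel(config: PhotometryConfig) -> np.ndarray:
    """Unit-peak double-exponential impulse response sampled at the
    configured rate; extends until it has decayed below 1e-3 of its peak."""
    tau_r, tau_d = config.kernel_tau_rise, config.kernel_tau_decay
    if not tau_d > tau_r >= 0:
        raise ValueError("require kernel_tau_decay > kernel_tau_rise >= 0")
    fs = config.sampling_rate
    n = max(int(np.ceil(fs * tau_d * np.log(1e3))) + 2, 4)
    while True:
        t = np.arange(n) / fs
        if tau_r <= 1e-12:
            k = np.exp(-t / tau_d)
        else:
            k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
        peak = k.max()
        k = k / peak
        if k[-1] < 1e-3:
            return k
        n *= 2


def trial_amplitude(
    hypothesis: str,
    choice: str,
    dq_chosen: float,
    dq_contra: float,
    config: PhotometryConfig,
) -> float:
    """Noise-free transient amplitude at lever presentation for one trial."""
    if hypothesis == "contra_value":
        return config.value_gain * dq_contra
    if hypothesis == "chosen_value":
        return config.value_gain * dq_chosen
    if hypothesis == "chosen_value_plus_movement":
        return config.value_gain * dq_chosen \
            + (config.movement_gain if choice == CONTRA else 0.0)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def _smooth_drift(n: int, config: PhotometryConfig, rng: np.random.Generator) -> np.ndarray:
    """Slow fractional baseline wander: white noise low-passed at
    1/drift_timescale Hz, rescaled to SD = drift_amplitude."""
    if config.drift_amplitude <= 0 or n < 30:
        return np.zeros(n)
    cutoff = 1.0 / config.drift_timescale
    nyq = config.sampling_rate / 2.0
    b, a = butter(2, min(cutoff / nyq, 0.99))
    x = rng.standard_normal(n + 2 * n)
    y = filtfilt(b, a, x)[n:2 * n]
    sd = y.std()
    if sd == 0:
        return np.zeros(n)
    return config.drift_amplitude * (y - y.mean()) / sd


def synthesize_trace(
    trials: pd.DataFrame,
    qtraj: pd.DataFrame,
    config: PhotometryConfig,
    rng: np.random.Generator | None = None,
) -> PhotometryTrace:
    """Generate the raw-fluorescence trace for one site's trial table.

    ``trials`` and ``qtraj`` must be row-aligned (same index). Transients are
    placed at ``t_lever_present`` with hypothesis-dependent amplitudes; under
    the movement hypothesis an additional movement transient is placed at
    ``t_lever_press`` (sign-flipped when ``movement_reversal`` is set).
    Timestamps are seconds from each session's start.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if len(trials) != len(qtraj) or not trials.index.equals(qtraj.index):
        raise ValueError("trials and qtraj are not row-aligned")
    site_ids = trials["site_id"].unique()
    if len(site_ids) != 1:
        raise ValueError("synthesize_trace expects a single site's trials")

    fs = config.sampling_rate
    kernel = calcium_kernel(config)
    chunks, offsets, session_ids = [], [], []
    pos = 0
    for session_id, df in trials.groupby("session_id", sort=False):
        t_end = float(np.nanmax(df[["t_lever_present", "t_outcome"]].to_numpy())) + 5.0
        n = int(np.ceil(t_end * fs)) + len(kernel)
        impulses = np.zeros(n)
        for idx, row in df.iterrows():
            if row["abandoned"]:
                continue
            amp = trial_amplitude(
                config.hypothesis, row["choice"],
                float(qtraj.at[idx, "dq_chosen"]), float(qtraj.at[idx, "dq_contra"]),
                config,
            )
            k_present = int(round(row["t_lever_present"] * fs))
            impulses[k_present] += amp
            if config.hypothesis == "chosen_value_plus_movement" and row["choice"] == CONTRA:
                k_press = int(round(row["t_lever_press"] * fs))
                sign = -1.0 if config.movement_reversal else 1.0
                impulses[k_press] += sign * config.movement_gain
        dff = np.convolve(impulses, kernel)[:n]
        dff += _smooth_drift(n, config, rng)
        if config.noise_sd > 0:
            dff += config.noise_sd * rng.standard_normal(n)
        chunks.append(config.baseline_f * (1.0 + dff))
        offsets.append(pos)
        session_ids.append(session_id)
        pos += n
    return PhotometryTrace(
        site_id=str(site_ids[0]), sampling_rate=fs,
        samples=np.concatenate(chunks),
        session_offsets=offsets, session_ids=session_ids,
    )
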