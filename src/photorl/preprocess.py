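"""Photometry preprocessing: high-pass FIR filtering, dF/F, per-site
z-scoring, and event-locked epoch extraction on the 15 Hz grid.

The preprocessing chain mirrors standard practice for slow-drifting bulk
fluorescence recordings: a linear-phase FIR high-pass (passband 0.375 Hz,
stopband 0.075 Hz, >= 10 dB stopband attenuation) removes baseline and
drift; dF/F is the filtered signal divided by the mean of the *unfiltered*
signal over the site's full concatenated record; z-scoring uses the full
record's mean and SD per site. Epochs span 1 s before to 2 s after the
alignment event: 15 pre-event + 30 post-event samples = 45 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin, freqz

from .photometry import PhotometryTrace

__all__ = [
    "FilterSpec",
    "EpochMatrix",
    "design_highpass_fir",
    "filter_attenuation_db",
    "apply_filter",
    "compute_dff",
    "zscore_site",
    "extract_epochs",
    "event_sample_indices",
    "preprocess_trace",
    "EPOCH_PRE",
    "EPOCH_POST",
]

EPOCH_PRE = 15   # samples before the event
EPOCH_POST = 30  # samples from the event onward (event sample included)


class FilterDesignError(RuntimeError):
    """Raised when no FIR of acceptable order meets the spec."""


@dataclass
class FilterSpec:
    passband_hz: float = 0.375
    stopband_hz: float = 0.075
    stopband_atten_db: float = 10.0
    sampling_rate: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.stopband_hz < self.passband_hz < self.sampling_rate / 2):
            raise ValueError("require 0 < stopband < passband < Nyquist")
        if self.stopband_atten_db <= 0:
            raise ValueError("stopband_atten_db must be > 0")


def design_highpass_fir(spec: FilterSpec, max_taps: int = 8191) -> np.ndarray:
    """Linear-phase high-pass FIR meeting ``spec``.

    A Hamming-window design with cutoff at the passband/stopband midpoint;
    the (odd) tap count grows geometrically from the standard transition-width
    estimate (~3.3 / normalized transition width) until the realized response
    is at or below -stopband_atten_db at the stopband edge and within
    +/- 1 dB of unity everywhere at or above the passband edge.
    """
    fs = spec.sampling_rate
    cutoff = 0.5 * (spec.passband_hz + spec.stopband_hz)
    width = (spec.passband_hz - spec.stopband_hz) / fs
    n = int(np.ceil(3.3 / width)) | 1
    while n <= max_taps:
        taps = firwin(n, cutoff, fs=fs, pass_zero=False, window="hamming")
        if (filter_attenuation_db(taps, spec.stopband_hz, fs) >= spec.stopband_atten_db
                and _passband_ok(taps, spec)):
            return taps
        n = (2 * n) | 1
    raise FilterDesignError(f"no FIR up to {max_taps} taps meets the spec {spec}")


def filter_attenuation_db(taps: np.ndarray, freq_hz: float, fs: float) -> float:
    """Attenuation (positive dB below unity gain) of the filter at one frequency."""
    _, h = freqz(taps, worN=[2 * np.pi * freq_hz / fs])
    return float(-20.0 * np.log10(np.abs(h[0])))


def _passband_ok(taps: np.ndarray, spec: FilterSpec) -> bool:
    fs = spec.sampling_rate
    f = np.linspace(spec.passband_hz, fs / 2 * 0.999, 512)
    _, h = freqz(taps, worN=2 * np.pi * f / fs)
    db = 20.0 * np.log10(np.abs(h))
    return bool(np.all(np.abs(db) <= 1.0))


def apply_filter(x: np.ndarray, taps: np.ndarray, zero_phase: bool = True) -> np.ndarray:
    """Apply the FIR per session segment.

    Zero-phase (forward-backward, reflection-padded) by default so
    event-locked features are not delayed; ``zero_phase=False`` gives the
    causal single-pass alternative (group delay (n_taps - 1)/2 samples).
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * len(taps):
        raise ValueError(f"trace of {len(x)} samples too short for a "
                         f"{len(taps)}-tap filter (need > 3x taps)")
    if not zero_phase:
        from scipy.signal import lfilter
        return lfilter(taps, [1.0], x)
    return filtfilt(taps, [1.0], x, padtype="even", padlen=len(taps))


def compute_dff(raw: np.ndarray, filtered: np.ndarray) -> np.ndarray:
    """dF/F: high-pass-filtered signal divided by the mean of the raw signal
    over the site's full record."""
    m = float(np.mean(raw))
    if m <= 0:
        raise ValueError("mean of raw trace must be positive")
    return np.asarray(filtered, dtype=float) / m


def zscore_site(dff: np.ndarray) -> np.ndarray:
    """z-score using the full-record mean and SD of one site."""
    dff = np.asarray(dff, dtype=float)
    sd = dff.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (dff - dff.mean()) / sd


def preprocess_trace(trace: PhotometryTrace, spec: FilterSpec | None = None) -> np.ndarray:
    """Full chain for one site: per-session high-pass filter, then dF/F with
    the full-record raw mean, then full-record z-scoring."""
    spec = spec or FilterSpec(sampling_rate=trace.sampling_rate)
    taps = design_highpass_fir(spec)
    filtered = np.empty_like(trace.samples)
    for a, b in trace.session_bounds():
        filtered[a:b] = apply_filter(trace.samples[a:b], taps)
    return zscore_site(compute_dff(trace.samples, filtered))


@dataclass
class EpochMatrix:
    """Trials x 45 matrix of event-locked z-scored dF/F.

    ``trial_index_map`` holds the trial-table index labels of the rows kept;
    ``dropped`` those excluded because their window left the trace or
    crossed a session boundary (never zero-padded).
    """

    values: np.ndarray
    time_axis: np.ndarray
    alignment_event: str
    trial_index_map: np.ndarray
    dropped: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def event_sample_indices(
    trace: PhotometryTrace, trials: pd.DataFrame, event: str
) -> pd.Series:
    """Map each trial's event timestamp (seconds from session start) to a
    global sample index on the trace's grid (nearest sample). NaN timestamps
    (abandoned trials) map to -1."""
    col = f"t_{event}"
    if col not in trials.columns:
        raise ValueError(f"unknown alignment event {event!r}")
    offsets = dict(zip(trace.session_ids, trace.session_offsets))
    out = np.full(len(trials), -1, dtype=np.int64)
    for i, (_, row) in enumerate(trials.iterrows()):
        t = row[col]
        if not np.isfinite(t):
            continue
        base = offsets.get(row["session_id"])
        if base is None:
            raise ValueError(f"session {row['session_id']!r} not present in trace")
        out[i] = base + int(round(t * trace.sampling_rate))
    return pd.Series(out, index=trials.index)


def extract_epochs(
    z: np.ndarray,
    event_samples: pd.Series | np.ndarray,
    alignment_event: str = "lever_present",
    sampling_rate: float = 15.0,
    session_offsets: list | None = None,
) -> EpochMatrix:
    """Cut 45-sample windows (15 pre, 30 from the event on) around each event.

    ``event_samples`` are global sample indices (negative = no event, e.g.
    abandoned trials). Windows that leave the trace or straddle a session
    boundary are dropped and reported in ``EpochMatrix.dropped``.
    """
    if isinstance(event_samples, pd.Series):
        labels = event_samples.index.to_numpy()
        ks = event_samples.to_numpy()
    else:
        ks = np.asarray(event_samples)
        labels = np.arange(len(ks))
    if len(ks) == 0:
        raise ValueError("empty event list")
    n = len(z)
    edges = np.asarray(sorted(set((session_offsets or [0])) | {n}))
    rows, kept, dropped = [], [], []
    for label, k in zip(labels, ks):
        k = int(k)
        lo, hi = k - EPOCH_PRE, k + EPOCH_POST
        if k < 0 or lo < 0 or hi > n:
            dropped.append(label)
            continue
        seg = np.searchsorted(edges, k, side="right")
        if lo < edges[seg - 1] or hi > edges[seg]:
            dropped.append(label)
            continue
        rows.append(z[lo:hi])
        kept.append(label)
    time_axis = np.arange(-EPOCH_PRE, EPOCH_POST) / sampling_rate
    values = np.vstack(rows) if rows else np.empty((0, EPOCH_PRE + EPOCH_POST))
    return EpochMatrix(values=values, time_axis=time_axis,
                       alignment_event=alignment_event,
                       trial_index_map=np.asarray(kept), dropped=dropped)
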