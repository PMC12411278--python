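"""Odor-onset hyperpolarization detection and theta phase-reset metrics.

The trial's raw (non-de-spiked) trace is lightly smoothed, z-scored against
the 500 ms pre-odor baseline to give ``S``, and the first merged run of
``S < -1`` samples intersecting the first odor is the candidate event.  It
counts as significant when it lasts more than 50 ms and spends more than
10 ms below ``S < -3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .io_model import CellSession, TrialRecord
from .preprocess import SAVGOL_WINDOW, despike, theta_extract

__all__ = [
    "HyperpolEvent",
    "HyperpolSummary",
    "detect_hyperpolarization",
    "summarize_hyperpol",
    "phase_reset_variance",
]

BASELINE_MS = 500
ENTER_SD = -1.0
DEEP_SD = -3.0
MIN_DURATION_MS = 50
MIN_DEEP_MS = 10
MERGE_GAP_MS = 20
PRE_ONSET_TOLERANCE_MS = 20  # candidate runs may begin slightly before the odor


@dataclass
class HyperpolEvent:
    """Times are ms relative to first-odor onset; amplitude is the minimum
    of the baseline-z-scored trace (negative, in baseline s.d. units)."""

    onset_ms: float
    trough_ms: float
    duration_ms: float
    amplitude_sd: float
    significant: bool

    def validate(self) -> None:
        if not (self.onset_ms <= self.trough_ms <= self.onset_ms + self.duration_ms):
            raise ValueError("trough must lie inside the event")
        if self.significant and not (
            self.duration_ms > MIN_DURATION_MS and self.amplitude_sd < DEEP_SD
        ):
            raise ValueError("significant event violates duration/amplitude rule")


@dataclass
class HyperpolSummary:
    occurrence_rate: float
    mean_amplitude_sd: Optional[float]
    mean_onset_ms: Optional[float]
    mean_trough_ms: Optional[float]
    mean_duration_ms: Optional[float]
    post_depolarization: Optional[float]
    fixed_window_amplitude: list[float]  # per-trial min S in first 200 ms
    events: list[Optional[HyperpolEvent]]


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))[0]
    return list(zip(idx[0::2], idx[1::2]))


def baseline_z(trial: TrialRecord, savgol_window: int = SAVGOL_WINDOW) -> np.ndarray:
    """Smoothed trace z-scored to the 500-ms pre-odor baseline (``S``)."""
    x = np.asarray(trial.dff, dtype=float)
    if len(x) > savgol_window:
        x = savgol_filter(x, savgol_window, 1)
    onset = trial.odor1_onset
    if onset < BASELINE_MS:
        raise ValueError("trial needs >= 500 ms pre-odor baseline")
    base = x[onset - BASELINE_MS: onset]
    sd = base.std()
    if sd <= 1e-12 * max(1.0, abs(base.mean())):
        raise ValueError("degenerate trace: zero baseline s.d.")
    return (x - base.mean()) / sd


def detect_hyperpolarization(
    trial: TrialRecord, savgol_window: int = SAVGOL_WINDOW
) -> Optional[HyperpolEvent]:
    """Detect the candidate odor-onset hyperpolarization of one trial.

    Returns None when no sub-threshold (``S < -1``) segment intersects the
    first odor window.  The earliest merged segment is taken even if it
    starts up to 20 ms before odor onset (merge tolerance).
    """
    S = baseline_z(trial, savgol_window)
    onset, offset = trial.odor1_onset, trial.odor1_offset
    # sub-threshold runs during the odor window (segments may begin up to
    # the merge tolerance before odor onset)
    mask = S < ENTER_SD
    mask[: onset - PRE_ONSET_TOLERANCE_MS] = False
    mask[offset:] = False
    runs = [(a, b) for a, b in _runs_below(mask) if b > onset]
    if not runs:
        return None
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < MERGE_GAP_MS:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    a, b = merged[0]
    seg = S[a:b]
    duration = float(b - a)
    deep_ms = float(np.sum(seg < DEEP_SD))
    significant = duration > MIN_DURATION_MS and deep_ms > MIN_DEEP_MS
    trough_idx = a + int(np.argmin(seg))
    ev = HyperpolEvent(
        onset_ms=float(a - onset),
        trough_ms=float(trough_idx - onset),
        duration_ms=duration,
        amplitude_sd=float(seg.min()),
        significant=significant,
    )
    ev.validate()
    return ev


def summarize_hyperpol(
    session: CellSession, savgol_window: int = SAVGOL_WINDOW
) -> HyperpolSummary:
    """Per-cell summary: occurrence rate and moments over significant events,
    plus the per-trial fixed-window amplitude (min S in the first 200 ms)."""
    events: list[Optional[HyperpolEvent]] = []
    fixed: list[float] = []
    post_depol: list[float] = []
    for tr in session.trials:
        ev = detect_hyperpolarization(tr, savgol_window)
        events.append(ev)
        S = baseline_z(tr, savgol_window)
        onset, offset = tr.odor1_onset, tr.odor1_offset
        fixed.append(float(S[onset: onset + 200].min()))
        if ev is not None and ev.significant:
            end = int(onset + ev.onset_ms + ev.duration_ms)
            if end < offset:
                post_depol.append(float(S[end:offset].max()))
    sig = [e for e in events if e is not None and e.significant]
    rate = len(sig) / len(session.trials)

    def _mean(vals):
        return float(np.mean(vals)) if vals else None

    return HyperpolSummary(
        occurrence_rate=rate,
        mean_amplitude_sd=_mean([e.amplitude_sd for e in sig]),
        mean_onset_ms=_mean([e.onset_ms for e in sig]),
        mean_trough_ms=_mean([e.trough_ms for e in sig]),
        mean_duration_ms=_mean([e.duration_ms for e in sig]),
        post_depolarization=_mean(post_depol),
        fixed_window_amplitude=fixed,
        events=events,
    )


def phase_reset_variance(
    session: CellSession, phases: Optional[np.ndarray] = None
) -> np.ndarray:
    """Circular variance (1 - mean resultant length) of the instantaneous
    theta phase across trials, per millisecond.

    ``phases`` may pass precomputed per-trial phase rows (trials x time);
    otherwise each trial is de-spiked and theta-extracted here.  A phase
    reset shows as a transient variance dip after odor onset.
    """
    if session.n_trials < 3:
        raise ValueError("phase-reset variance needs >= 3 trials")
    if phases is None:
        rows = []
        for tr in session.trials:
            clean = despike(tr.dff, tr.spike_times)
            rows.append(theta_extract(clean).phase)
        phases = np.vstack(rows)
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] != session.n_trials:
        raise ValueError("phase matrix row count must match trial count")
    R = np.abs(np.exp(1j * phases).mean(axis=0))
    return 1.0 - R
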