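"""Fine-timescale (5-ms) odor-onset and rebound spiking analysis.

Rates are binned at 5 ms around the first odor and smoothed with a
three-point moving average for display; the onset window is
[30, 50) ms and the rebound window [200, 500) ms post-odor, compared
against the 500-ms pre-odor baseline.  Window membership is by bin start
time, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import CellSession, OdorDelayAxis
from .preprocess import RateMatrix, bin_spike_counts, moving_average

__all__ = ["FinescaleMetrics", "finescale_rates", "onset_rebound_metrics"]

FINE_BIN_MS = 5
ONSET_WINDOW_MS = (30, 50)
REBOUND_WINDOW_MS = (200, 500)
BASELINE_MS = 500
POST_MS = 1000


@dataclass
class FinescaleMetrics:
    onset_rate_hz: float
    rebound_rate_hz: float
    baseline_rate_hz: float
    onset_increase: float  # relative change vs baseline; NaN if baseline 0
    rebound_increase: float


def _fine_axis(session: CellSession) -> OdorDelayAxis:
    onset = session.trials[0].odor1_onset
    return OdorDelayAxis(
        start_ms=onset - BASELINE_MS, end_ms=onset + POST_MS, bin_ms=FINE_BIN_MS
    )


def finescale_rates(session: CellSession, smooth_points: int = 3) -> RateMatrix:
    """Per-trial 5-ms binned rates around the first odor, three-point
    moving-average smoothed."""
    axis = _fine_axis(session)
    rates = bin_spike_counts(session, axis) / (FINE_BIN_MS / 1000.0)
    desc = "none"
    if smooth_points > 1:
        rates = moving_average(rates, smooth_points, axis=1)
        desc = f"ma{smooth_points}"
    return RateMatrix(rates=rates, axis=axis, smoothing=desc)


def onset_rebound_metrics(session: CellSession) -> FinescaleMetrics:
    """Mean onset/rebound-window rates across trials and their relative
    change vs the 0.5-s pre-odor baseline (from raw spike counts, so window
    means recompute exactly)."""
    axis = _fine_axis(session)
    counts = bin_spike_counts(session, axis)
    starts = axis.edges[:-1] - session.trials[0].odor1_onset  # rel. odor onset

    def window_rate(lo: float, hi: float) -> float:
        sel = (starts >= lo) & (starts < hi)
        return float(counts[:, sel].mean() / (FINE_BIN_MS / 1000.0))

    base = window_rate(-BASELINE_MS, 0)
    onset = window_rate(*ONSET_WINDOW_MS)
    rebound = window_rate(*REBOUND_WINDOW_MS)
    if base == 0:
        warnings.warn("zero baseline rate; relative increases undefined")
        onset_inc = rebound_inc = float("nan")
    else:
        onset_inc = (onset - base) / base
        rebound_inc = (rebound - base) / base
    return FinescaleMetrics(
        onset_rate_hz=onset,
        rebound_rate_hz=rebound,
        baseline_rate_hz=base,
        onset_increase=onset_inc,
        rebound_increase=rebound_inc,
    )
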