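"""Temporal firing-field detection over the odor-delay interval.

A cell's per-trial rates (100-ms bins, five-point smoothed, z-scored per
trial over the interval) are split by initiating odor.  The observed
statistic per odor is the maximum over bins of the trial-mean rate; the
null is the same statistic after independently circularly shifting each
trial's rate vector by a random whole-bin offset up to half the interval,
repeated 1000 times.  Significance requires the observed maximum to exceed
the null's 95th percentile (strictly; ties are conservative).

Selectivity: SI = (R_A - R_B) / (R_A + R_B) from raw (Hz) mean rates at the
final field bin; cells significant for both odors, or with |SI| < 0.42, are
non-odor-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_model import CellSession, OdorDelayAxis, ODOR_DURATION_MS
from .preprocess import bin_rates, bin_spike_counts, moving_average

__all__ = [
    "FieldResult",
    "ShuffleNull",
    "detect_fields",
    "selectivity_index",
    "chance_selectivity",
    "rate_change_segments",
    "shuffled_max_null",
]

SI_THRESHOLD = 0.42
MERGE_DISTANCE_MS = 1000


@dataclass
class OdorFieldStat:
    significant: bool
    field_bin: int
    max_mean_rate: float  # z-units
    null_percentile: float  # 95th percentile of the shuffle null


@dataclass
class ShuffleNull:
    n_shuffles: int = 1000
    percentile: float = 95.0


@dataclass
class FieldResult:
    per_odor: dict[str, OdorFieldStat]
    category: str  # odorA-specific | odorB-specific | non-odor-specific | no-field
    final_field_bin: Optional[float]
    field_kind: Optional[str]  # odor | delay
    si: Optional[float]
    rate_a: Optional[float]  # Hz at the field bin
    rate_b: Optional[float]

    def validate(self) -> None:
        if self.si is not None and not (-1.0 - 1e-12 <= self.si <= 1.0 + 1e-12):
            raise ValueError("|SI| must be <= 1")
        sig = {o: s.significant for o, s in self.per_odor.items()}
        if self.category == "odorA-specific":
            assert sig.get("A") and not sig.get("B") and abs(self.si) >= SI_THRESHOLD
        elif self.category == "odorB-specific":
            assert sig.get("B") and not sig.get("A") and abs(self.si) >= SI_THRESHOLD
        elif self.category == "no-field":
            assert not any(sig.values())


def shuffled_max_null(
    rates: np.ndarray, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of max-over-bins trial-mean rate under per-trial
    independent circular shifts (uniform on +/- half the axis, whole bins)."""
    n_trials, n_bins = rates.shape
    half = n_bins // 2
    shifts = rng.integers(-half, half + 1, size=(n_shuffles, n_trials))
    col = np.arange(n_bins)
    # gather: shifted[s, i, b] = rates[i, (b - shift) % n_bins]
    idx = (col[None, None, :] - shifts[:, :, None]) % n_bins
    shifted = np.take_along_axis(
        np.broadcast_to(rates, (n_shuffles, n_trials, n_bins)), idx, axis=2
    )
    return shifted.mean(axis=1).max(axis=1)


def detect_fields(
    session: CellSession,
    axis: Optional[OdorDelayAxis] = None,
    null: Optional[ShuffleNull] = None,
    seed: int = 0,
    smooth_points: int = 5,
    rate_matrix: Optional[np.ndarray] = None,
) -> FieldResult:
    """Detect per-odor firing fields and classify the cell.

    ``rate_matrix`` (trials x bins, already smoothed/z-scored) overrides the
    spike-time front end, so extracellular rates (Gaussian 300-ms smoothing)
    or deconvolved calcium signals can reuse the same detector.
    """
    axis = axis or OdorDelayAxis()
    null = null or ShuffleNull()
    rng = np.random.default_rng(seed)

    if rate_matrix is not None:
        z = np.asarray(rate_matrix, dtype=float)
        if z.shape[0] != session.n_trials:
            raise ValueError("rate_matrix rows must match trial count")
        if z.shape[1] == axis.n_bins:
            # spike-based rates still available for the SI
            raw_hz = bin_rates(session, axis).rates
        else:
            raw_hz = z  # e.g. raw deconvolved signal; SI guarded below
    else:
        z = bin_rates(session, axis, smooth_points=smooth_points, zscore=True).rates
        # SI uses unsmoothed rates; smoothing is a detection-side device
        raw_hz = bin_rates(session, axis).rates

    odor_ids = np.array([t.odor1_id for t in session.trials])
    per_odor: dict[str, OdorFieldStat] = {}
    for odor in ("A", "B"):
        sel = odor_ids == odor
        if sel.sum() < 2:
            raise ValueError(f"need >= 2 trials initiated by odor {odor}")
        rates = z[sel]
        if np.allclose(rates, 0):
            warnings.warn(f"degenerate all-zero rates for odor {odor}; no field")
            per_odor[odor] = OdorFieldStat(False, 0, 0.0, 0.0)
            continue
        mean = rates.mean(axis=0)
        obs = float(mean.max())
        bin_idx = int(np.argmax(mean))  # argmax -> earliest on ties
        dist = shuffled_max_null(rates, null.n_shuffles, rng)
        p95 = float(np.percentile(dist, null.percentile))
        per_odor[odor] = OdorFieldStat(obs > p95, bin_idx, obs, p95)

    sig_a, sig_b = per_odor["A"].significant, per_odor["B"].significant

    # final field bin
    if sig_a and sig_b:
        ba, bb = per_odor["A"].field_bin, per_odor["B"].field_bin
        if abs(ba - bb) * axis.bin_ms <= MERGE_DISTANCE_MS:
            final_bin: Optional[float] = (ba + bb) / 2.0
        else:
            final_bin = float(
                ba if per_odor["A"].max_mean_rate >= per_odor["B"].max_mean_rate else bb
            )
    elif sig_a:
        final_bin = float(per_odor["A"].field_bin)
    elif sig_b:
        final_bin = float(per_odor["B"].field_bin)
    else:
        overall = z.mean(axis=0)
        final_bin = float(np.argmax(overall))

    # SI from raw rates at the final field bin
    bin_i = int(round(final_bin))
    bin_i = min(bin_i, raw_hz.shape[1] - 1)
    r_a = float(raw_hz[odor_ids == "A", bin_i].mean())
    r_b = float(raw_hz[odor_ids == "B", bin_i].mean())
    if r_a < 0 or r_b < 0:
        warnings.warn("negative field rates (z-scored input); SI undefined")
        si = None
    else:
        si = selectivity_index(r_a, r_b)

    if sig_a and sig_b:
        category = "non-odor-specific"
    elif sig_a:
        category = "odorA-specific" if si is not None and abs(si) >= SI_THRESHOLD else "non-odor-specific"
    elif sig_b:
        category = "odorB-specific" if si is not None and abs(si) >= SI_THRESHOLD else "non-odor-specific"
    else:
        category = "no-field"

    has_field = sig_a or sig_b
    field_kind = None
    if has_field:
        field_time = final_bin * axis.bin_ms
        field_kind = "odor" if field_time < ODOR_DURATION_MS else "delay"

    res = FieldResult(
        per_odor=per_odor,
        category=category,
        final_field_bin=final_bin,
        field_kind=field_kind,
        si=si,
        rate_a=r_a,
        rate_b=r_b,
    )
    res.validate()
    return res


def selectivity_index(rate_a: float, rate_b: float) -> Optional[float]:
    """SI = (R_A - R_B) / (R_A + R_B); None (flagged) when both rates are 0."""
    total = rate_a + rate_b
    if total <= 0:
        warnings.warn("both field rates are zero; SI undefined")
        return None
    return float((rate_a - rate_b) / total)


def chance_selectivity(
    session: CellSession,
    field_bin: int,
    axis: Optional[OdorDelayAxis] = None,
    seed: int = 0,
    n_reps: int = 1000,
    smooth_points: int = 5,
) -> np.ndarray:
    """Chance SI distribution from random ~50/50 trial splits at the field
    bin, 1000 repetitions (splits with an empty side are redrawn)."""
    axis = axis or OdorDelayAxis()
    rng = np.random.default_rng(seed)
    rates = bin_rates(session, axis, smooth_points=smooth_points).rates[:, field_bin]
    n = len(rates)
    out = np.empty(n_reps)
    for i in range(n_reps):
        while True:
            mask = rng.random(n) < 0.5
            if 0 < mask.sum() < n:
                break
        si = selectivity_index(float(rates[mask].mean()), float(rates[~mask].mean()))
        out[i] = np.nan if si is None else si
    return out


def rate_change_segments(session: CellSession) -> dict[str, float]:
    """Trial-averaged relative rate change per trial segment vs the 0.8-s
    pre-odor baseline.  Zero-baseline trials are excluded with a warning."""
    tr0 = session.trials[0]
    segments = {
        "odor1": (tr0.odor1_onset, tr0.odor1_offset),
        "delay": (tr0.odor1_offset, tr0.odor2_onset),
        "odor2": (tr0.odor2_onset, tr0.odor2_offset),
        "response": (tr0.odor2_offset, tr0.response_window_end),
    }
    baseline_win = (tr0.odor1_onset - 800, tr0.odor1_onset)
    changes: dict[str, list[float]] = {k: [] for k in segments}
    for tr in session.trials:
        base_rate = len(tr.spikes_in(*baseline_win)) / 0.8
        if base_rate == 0:
            warnings.warn("zero baseline rate; trial excluded from rate change")
            continue
        for name, (a, b) in segments.items():
            seg_rate = len(tr.spikes_in(a, b)) / ((b - a) / 1000.0)
            changes[name].append((seg_rate - base_rate) / base_rate)
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in changes.items()}
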