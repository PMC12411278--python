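"""Cross-session stability: odor-field turnover and trial-pair correlations.

Turnover is defined over odor fields (fields within the first-odor bins);
for each consecutive tracked session pair, "stable" cells held an odor
field on both days, "inflow" gained one, "outflow" lost one.  Cells tracked
for more than two sessions contribute each consecutive pair independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import CellSession, OdorDelayAxis
from .preprocess import bin_rates

__all__ = [
    "TurnoverResult",
    "CrossDayCorr",
    "turnover_rates",
    "cross_session_correlation",
    "correlation_vs_distance",
    "has_odor_field",
]


def has_odor_field(field_result) -> bool:
    """True when a FieldResult represents a significant odor field (delay
    fields do not count; a delay-to-odor transition is inflow)."""
    return (
        field_result is not None
        and field_result.category != "no-field"
        and field_result.field_kind == "odor"
    )


@dataclass
class PairTurnover:
    session_pair: tuple[int, int]
    stable_pct: float
    inflow_pct: float
    outflow_pct: float
    n_current_field: int  # denominator for stable/inflow
    n_previous_field: int  # denominator for outflow


@dataclass
class TurnoverResult:
    pairs: list[PairTurnover]

    @property
    def overall_stable_pct(self) -> float:
        num = sum(p.stable_pct * p.n_current_field / 100.0 for p in self.pairs)
        den = sum(p.n_current_field for p in self.pairs)
        return 100.0 * num / den if den else float("nan")

    @property
    def overall_retention_pct(self) -> float:
        """Stable cells over previous-day field cells, pooled over pairs
        (the complement of outflow: day-to-day odor-field retention)."""
        num = sum(p.stable_pct * p.n_current_field / 100.0 for p in self.pairs)
        den = sum(p.n_previous_field for p in self.pairs)
        return 100.0 * num / den if den else float("nan")


@dataclass
class CrossDayCorr:
    mean_correlation: float
    session_distance: int
    label: str  # trained-trained | pre-post


def turnover_rates(
    tracked_cells: Sequence[dict[int, object]]
) -> TurnoverResult:
    """Turnover percentages over consecutive session pairs.

    ``tracked_cells`` maps, per cell, session index -> FieldResult (or any
    object accepted by :func:`has_odor_field`); a missing session index
    means the cell was not imaged that day.
    """
    if not tracked_cells:
        raise ValueError("no tracked cells")
    all_sessions = sorted({d for cell in tracked_cells for d in cell})
    if len(all_sessions) < 2:
        raise ValueError("need >= 2 sessions")
    pairs: list[PairTurnover] = []
    for prev_d, d in zip(all_sessions[:-1], all_sessions[1:]):
        cur_field = prev_field = stable = inflow = outflow = 0
        tracked_any = False
        for cell in tracked_cells:
            if prev_d not in cell or d not in cell:
                continue
            tracked_any = True
            f_prev = has_odor_field(cell[prev_d])
            f_cur = has_odor_field(cell[d])
            if f_cur:
                cur_field += 1
                if f_prev:
                    stable += 1
                else:
                    inflow += 1
            if f_prev:
                prev_field += 1
                if not f_cur:
                    outflow += 1
        if not tracked_any:
            warnings.warn(f"no cells tracked across sessions {prev_d}->{d}; pair skipped")
            continue
        pairs.append(
            PairTurnover(
                session_pair=(prev_d, d),
                stable_pct=100.0 * stable / cur_field if cur_field else float("nan"),
                inflow_pct=100.0 * inflow / cur_field if cur_field else float("nan"),
                outflow_pct=100.0 * outflow / prev_field if prev_field else float("nan"),
                n_current_field=cur_field,
                n_previous_field=prev_field,
            )
        )
    return TurnoverResult(pairs=pairs)


def cross_session_correlation(
    sess_a: CellSession,
    sess_b: CellSession,
    axis: Optional[OdorDelayAxis] = None,
    smooth_points: int = 5,
) -> CrossDayCorr:
    """Mean Pearson correlation over all trial pairs between two sessions of
    the same cell, on per-trial z-scored odor-delay firing rates."""
    if sess_a.cell_id != sess_b.cell_id:
        raise ValueError("sessions must come from the same cell")
    axis = axis or OdorDelayAxis()
    za = bin_rates(sess_a, axis, smooth_points=smooth_points, zscore=True).rates
    zb = bin_rates(sess_b, axis, smooth_points=smooth_points, zscore=True).rates
    vals = []
    for ra in za:
        if ra.std() == 0:
            continue
        for rb in zb:
            if rb.std() == 0:
                continue
            vals.append(float(np.corrcoef(ra, rb)[0, 1]))
    label = (
        "trained-trained"
        if sess_a.training_state == "trained" and sess_b.training_state == "trained"
        else "pre-post"
    )
    return CrossDayCorr(
        mean_correlation=float(np.mean(vals)) if vals else float("nan"),
        session_distance=abs(sess_b.session_index - sess_a.session_index),
        label=label,
    )


def correlation_vs_distance(pairs: Sequence[CrossDayCorr]) -> tuple[float, float]:
    """Cohort-level Spearman rank correlation of mean pairwise correlation
    against session distance; returns (rho, p)."""
    r = [p.mean_correlation for p in pairs]
    d = [p.session_distance for p in pairs]
    rho, p = stats.spearmanr(r, d)
    return float(rho), float(p)
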