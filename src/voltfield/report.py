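"""Cohort-level summary assembly from per-cell stage tables.

Joins the CSV tables written by the pipeline stages and computes, per cell
class, the field-category breakdown, mean |SI|, hyperpolarization
occurrence/amplitude summaries and decoding summaries.  Aggregates are pure
functions of the per-cell tables (no hidden state) and are re-emitted as
``summary.json`` and ``summary.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CohortSummary", "build_summary"]

FIELD_CATEGORIES = ("odorA-specific", "odorB-specific", "non-odor-specific", "no-field")

# table file -> CLI stage that produces it
STAGE_FOR_TABLE = {
    "fields.csv": "voltfield fields",
    "hyperpol.csv": "voltfield hyperpol",
    "decode.csv": "voltfield decode",
    "turnover.csv": "voltfield multiday",
    "finescale.csv": "voltfield finescale",
}


@dataclass
class CohortSummary:
    per_class: dict[str, dict] = dc_field(default_factory=dict)
    n_cells: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"n_cells": self.n_cells, "per_class": self.per_class},
            indent=2,
            sort_keys=True,
        )


def _load(results_dir: Path, name: str, required: bool) -> Optional[pd.DataFrame]:
    path = results_dir / name
    if not path.exists():
        if required:
            raise FileNotFoundError(
                f"missing {name}; run `{STAGE_FOR_TABLE[name]}` first"
            )
        return None
    return pd.read_csv(path)


def build_summary(results_dir, out_dir=None) -> CohortSummary:
    """Aggregate per-cell tables under ``results_dir`` into a cohort summary.

    ``fields.csv`` is required; hyperpolarization, decoding, turnover and
    fine-scale tables are folded in when present.  Writes ``summary.json``
    and ``summary.csv`` to ``out_dir`` (default: ``results_dir``).
    """
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir is not None else results_dir
    fields = _load(results_dir, "fields.csv", required=True)
    hyperpol = _load(results_dir, "hyperpol.csv", required=False)
    decode = _load(results_dir, "decode.csv", required=False)
    finescale = _load(results_dir, "finescale.csv", required=False)

    summary = CohortSummary(n_cells=len(fields))
    rows = []
    for cls, grp in fields.groupby("cell_class"):
        n = len(grp)
        cat_pct = {
            c: 100.0 * float((grp["category"] == c).sum()) / n for c in FIELD_CATEGORIES
        }
        entry: dict = {
            "n_cells": n,
            "pct_field_cells": 100.0 - cat_pct["no-field"],
            "category_pct": cat_pct,
            "mean_abs_si": float(np.nanmean(np.abs(grp["si"].to_numpy(dtype=float)))),
        }
        if hyperpol is not None:
            h = hyperpol[hyperpol["cell_class"] == cls]
            if len(h):
                entry["hyperpol"] = {
                    "mean_occurrence_rate": float(h["occurrence_rate"].mean()),
                    "mean_amplitude_sd": float(
                        np.nanmean(h["mean_amplitude_sd"].to_numpy(dtype=float))
                    ),
                }
        if decode is not None:
            d = decode[decode["cell_class"] == cls]
            if len(d):
                entry["decoding"] = {
                    "mean_time_error_ms": float(d["time_error_ms"].mean()),
                    "mean_odor_accuracy": float(d["odor_accuracy"].mean()),
                }
        if finescale is not None:
            f = finescale[finescale["cell_class"] == cls]
            if len(f):
                entry["finescale"] = {
                    "mean_onset_increase": float(
                        np.nanmean(f["onset_increase"].to_numpy(dtype=float))
                    ),
                    "mean_rebound_increase": float(
                        np.nanmean(f["rebound_increase"].to_numpy(dtype=float))
                    ),
                }
        summary.per_class[str(cls)] = entry
        row = {"cell_class": cls, "n_cells": n, "mean_abs_si": entry["mean_abs_si"]}
        row.update({f"pct_{c}": v for c, v in cat_pct.items()})
        rows.append(row)

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(summary.to_json())
    pd.DataFrame(rows).sort_values("cell_class").to_csv(out_dir / "summary.csv", index=False)
    return summary
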