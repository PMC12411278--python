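"""Canonical data model for trial-structured recordings.

A recording session is a :class:`CellSession`: one cell on one day, holding an
ordered list of :class:`TrialRecord` objects.  Each trial carries a 1 kHz
fluorescence-ratio trace (``dff``), detected spike times, a 1 kHz locomotion
signal, and the odor/event timing layout of the delayed non-match-to-sample
trial.  Sessions round-trip losslessly through a simple HDF5 layout.

Timing convention: milliseconds from trial start, ``t = 0`` at recording
onset; the first odor arrives at 1000 ms; all windows are half-open
``[a, b)``.  Spike times are frame-aligned integers (1 kHz acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "TrialRecord",
    "CellSession",
    "OdorDelayAxis",
    "load_session",
    "save_session",
    "concatenate_recordings",
]

CELL_CLASSES = ("PV", "SST", "PYR", "UNIT")
TRAINING_STATES = ("naive", "trained")
ODOR_IDS = ("A", "B")

ODOR1_ONSET_MS = 1000
ODOR_DURATION_MS = 1000
DELAY_MS = 5000


class FormatError(Exception):
    """File does not follow the expected HDF5 layout."""


class ValidationError(Exception):
    """A domain invariant is violated."""


@dataclass
class TrialRecord:
    """One DNMS trial.

    ``dff`` and ``locomotion`` are sampled at 1 kHz; ``spike_times`` are
    integer milliseconds from trial start, strictly increasing.
    """

    dff: np.ndarray
    spike_times: np.ndarray
    locomotion: np.ndarray
    odor1_id: str
    odor2_id: str
    odor1_onset: int = ODOR1_ONSET_MS
    odor1_offset: int = ODOR1_ONSET_MS + ODOR_DURATION_MS
    odor2_onset: int = ODOR1_ONSET_MS + ODOR_DURATION_MS + DELAY_MS
    odor2_offset: int = ODOR1_ONSET_MS + 2 * ODOR_DURATION_MS + DELAY_MS
    response_window_end: int = 11000
    licks: Optional[np.ndarray] = None
    stim_window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=np.float64)
        self.locomotion = np.asarray(self.locomotion, dtype=np.float64)
        self.spike_times = np.asarray(self.spike_times, dtype=np.int64)
        self.odor1_id = str(self.odor1_id)
        self.odor2_id = str(self.odor2_id)
        if self.licks is not None:
            self.licks = np.asarray(self.licks, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.dff)

    def validate(self, label: str = "trial") -> None:
        if self.dff.ndim != 1 or self.locomotion.ndim != 1:
            raise ValidationError(f"{label}: dff and locomotion must be 1-D")
        if len(self.dff) != len(self.locomotion):
            raise ValidationError(
                f"{label}: dff length {len(self.dff)} != locomotion length "
                f"{len(self.locomotion)}"
            )
        st = self.spike_times
        if st.size and (np.any(np.diff(st) <= 0)):
            raise ValidationError(f"{label}: spike_times not strictly increasing")
        if st.size and (st[0] < 0 or st[-1] >= len(self.dff)):
            raise ValidationError(f"{label}: spike_times outside [0, trial length)")
        if self.odor1_id not in ODOR_IDS or self.odor2_id not in ODOR_IDS:
            raise ValidationError(f"{label}: odor ids must be in {ODOR_IDS}")
        if self.odor1_onset != ODOR1_ONSET_MS:
            raise ValidationError(
                f"{label}: odor1_onset must be {ODOR1_ONSET_MS} ms (got {self.odor1_onset})"
            )
        if self.odor1_offset - self.odor1_onset != ODOR_DURATION_MS:
            raise ValidationError(f"{label}: odor1 duration must be {ODOR_DURATION_MS} ms")
        if self.odor2_offset - self.odor2_onset != ODOR_DURATION_MS:
            raise ValidationError(f"{label}: odor2 duration must be {ODOR_DURATION_MS} ms")
        if self.odor2_onset - self.odor1_offset != DELAY_MS:
            raise ValidationError(f"{label}: delay must be {DELAY_MS} ms")
        if not (
            self.odor2_offset <= self.response_window_end <= len(self.dff)
        ):
            raise ValidationError(f"{label}: response_window_end out of bounds")

    def spikes_in(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Spike times falling in the half-open window [start_ms, end_ms)."""
        st = self.spike_times
        return st[(st >= start_ms) & (st < end_ms)]


@dataclass
class CellSession:
    """All trials from one cell on one day."""

    cell_id: str
    mouse_id: str
    cell_class: str
    training_state: str
    session_index: int
    sample_rate: float
    trials: list[TrialRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"cell_class must be one of {CELL_CLASSES}")
        if self.training_state not in TRAINING_STATES:
            raise ValidationError(f"training_state must be one of {TRAINING_STATES}")
        if self.session_index < 0:
            raise ValidationError("session_index must be non-negative")
        if not self.trials:
            raise ValidationError("session must contain at least one trial")
        layout = None
        for k, tr in enumerate(self.trials):
            tr.validate(label=f"trial {k}")
            this = (
                tr.odor1_onset,
                tr.odor1_offset,
                tr.odor2_onset,
                tr.odor2_offset,
                tr.response_window_end,
            )
            if layout is None:
                layout = this
            elif this != layout:
                raise ValidationError(f"trial {k}: event-timing layout differs from trial 0")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_by_odor(self, odor: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.odor1_id == odor]


@dataclass(frozen=True)
class OdorDelayAxis:
    """Binned time axis over an interval of the trial.

    Defaults to the odor-delay interval (first odor onset through the end of
    the delay, 6000 ms) at 100-ms bins; the fine-timescale analyses use 5-ms
    bins.  Bins are half-open ``[t, t + bin_ms)``.
    """

    start_ms: int = ODOR1_ONSET_MS
    end_ms: int = ODOR1_ONSET_MS + ODOR_DURATION_MS + DELAY_MS
    bin_ms: int = 100

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValidationError("axis end must exceed start")
        if self.bin_ms <= 0:
            raise ValidationError("bin_ms must be positive")
        if (self.end_ms - self.start_ms) % self.bin_ms != 0:
            raise ValidationError(
                f"axis length {self.end_ms - self.start_ms} not divisible by bin_ms {self.bin_ms}"
            )

    @property
    def n_bins(self) -> int:
        return (self.end_ms - self.start_ms) // self.bin_ms

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.start_ms, self.end_ms + self.bin_ms, self.bin_ms)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.bin_ms / 2.0


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def _create_ds(group: h5py.Group, name: str, data: np.ndarray) -> None:
    # track_times=False keeps repeated saves byte-identical
    group.create_dataset(name, data=data, track_times=False)


def _create_group(parent, name: str) -> h5py.Group:
    gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    gid = h5py.h5g.create(parent.id, name.encode(), gcpl=gcpl)
    return h5py.Group(gid)


def save_session(session: CellSession, path) -> None:
    """Write a validated session to ``path`` (HDF5, deterministic payload)."""
    session.validate()
    path = Path(path)
    fcpl = h5py.h5p.create(h5py.h5p.FILE_CREATE)
    fcpl.set_obj_track_times(False)  # timestamp-free root group
    fid = h5py.h5f.create(str(path).encode(), h5py.h5f.ACC_TRUNC, fcpl=fcpl)
    with h5py.File(fid) as f:
        meta = _create_group(f, "meta")
        meta.attrs["cell_id"] = session.cell_id
        meta.attrs["mouse_id"] = session.mouse_id
        meta.attrs["cell_class"] = session.cell_class
        meta.attrs["training_state"] = session.training_state
        meta.attrs["session_index"] = int(session.session_index)
        meta.attrs["sample_rate"] = float(session.sample_rate)
        trials = _create_group(f, "trials")
        for k, tr in enumerate(session.trials):
            g = _create_group(trials, str(k))
            _create_ds(g, "dff", tr.dff)
            _create_ds(g, "locomotion", tr.locomotion)
            _create_ds(g, "spike_times", tr.spike_times)
            if tr.licks is not None:
                _create_ds(g, "licks", tr.licks)
            g.attrs["odor1_id"] = tr.odor1_id
            g.attrs["odor2_id"] = tr.odor2_id
            g.attrs["odor1_onset"] = int(tr.odor1_onset)
            g.attrs["odor1_offset"] = int(tr.odor1_offset)
            g.attrs["odor2_onset"] = int(tr.odor2_onset)
            g.attrs["odor2_offset"] = int(tr.odor2_offset)
            g.attrs["response_window_end"] = int(tr.response_window_end)
            if tr.stim_window is not None:
                g.attrs["stim_onset"] = int(tr.stim_window[0])
                g.attrs["stim_offset"] = int(tr.stim_window[1])


def _require(container, key: str, path) -> object:
    if key not in container:
        raise FormatError(f"{path}: missing '{key}'")
    return container[key]


def load_session(path) -> CellSession:
    """Read a session written by :func:`save_session` and validate it."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    with h5py.File(path, "r") as f:
        meta = _require(f, "meta", path)
        attrs = meta.attrs
        for key in (
            "cell_id",
            "mouse_id",
            "cell_class",
            "training_state",
            "session_index",
            "sample_rate",
        ):
            if key not in attrs:
                raise FormatError(f"{path}: /meta missing attribute '{key}'")
        trials_grp = _require(f, "trials", path)
        trials: list[TrialRecord] = []
        for k in sorted(trials_grp.keys(), key=int):
            g = trials_grp[k]
            for ds in ("dff", "locomotion", "spike_times"):
                if ds not in g:
                    raise FormatError(f"{path}: /trials/{k} missing dataset '{ds}'")
            stim = None
            if "stim_onset" in g.attrs:
                stim = (int(g.attrs["stim_onset"]), int(g.attrs["stim_offset"]))
            trials.append(
                TrialRecord(
                    dff=g["dff"][()],
                    locomotion=g["locomotion"][()],
                    spike_times=g["spike_times"][()],
                    odor1_id=str(g.attrs["odor1_id"]),
                    odor2_id=str(g.attrs["odor2_id"]),
                    odor1_onset=int(g.attrs["odor1_onset"]),
                    odor1_offset=int(g.attrs["odor1_offset"]),
                    odor2_onset=int(g.attrs["odor2_onset"]),
                    odor2_offset=int(g.attrs["odor2_offset"]),
                    response_window_end=int(g.attrs["response_window_end"]),
                    licks=g["licks"][()] if "licks" in g else None,
                    stim_window=stim,
                )
            )
        session = CellSession(
            cell_id=str(attrs["cell_id"]),
            mouse_id=str(attrs["mouse_id"]),
            cell_class=str(attrs["cell_class"]),
            training_state=str(attrs["training_state"]),
            session_index=int(attrs["session_index"]),
            sample_rate=float(attrs["sample_rate"]),
            trials=trials,
        )
    session.validate()
    return session


def concatenate_recordings(parts: Sequence[CellSession]) -> CellSession:
    """Join successive recordings of the same cell into one session.

    All processed sets of trials from one neuron in a session are treated as
    one continuous recording; trial counts are additive.
    """
    if not parts:
        raise ValidationError("need at least one part")
    first = parts[0]
    for p in parts[1:]:
        for attr in ("cell_id", "session_index", "sample_rate"):
            if getattr(p, attr) != getattr(first, attr):
                raise ValidationError(
                    f"mismatched {attr}: {getattr(p, attr)!r} != {getattr(first, attr)!r}"
                )
    merged = replace(first, trials=[t for p in parts for t in p.trials])
    merged.validate()
    return merged
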