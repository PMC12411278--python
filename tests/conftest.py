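"""Shared fixtures: hand-built deterministic sessions and small synthetic ones."""

from __future__ import annotations

import numpy as np
import pytest

from voltfield.io_model import CellSession, TrialRecord
from voltfield.synthgen import SynthConfig, generate_cell_session

TRIAL_LEN = 11000


def make_trial(
    spike_times=(),
    odor1_id="A",
    odor2_id="B",
    dff=None,
    locomotion=None,
    n=TRIAL_LEN,
    licks=None,
):
    return TrialRecord(
        dff=np.zeros(n) if dff is None else np.asarray(dff, dtype=float),
        spike_times=np.asarray(sorted(spike_times), dtype=np.int64),
        locomotion=np.zeros(n) if locomotion is None else np.asarray(locomotion, dtype=float),
        odor1_id=odor1_id,
        odor2_id=odor2_id,
        licks=None if licks is None else np.asarray(licks, dtype=np.int64),
    )


def make_session(trials, cell_id="c0", cell_class="PV", session_index=0, training_state="trained"):
    return CellSession(
        cell_id=cell_id,
        mouse_id="m0",
        cell_class=cell_class,
        training_state=training_state,
        session_index=session_index,
        sample_rate=1000.0,
        trials=list(trials),
    )


def regular_spikes(period_ms, n=TRIAL_LEN, start=0):
    """Deterministic evenly spaced spike train."""
    return np.arange(start, n, period_ms, dtype=np.int64)


@pytest.fixture(scope="session")
def synth_session():
    """A moderately rich synthetic session shared by read-only tests."""
    cfg = SynthConfig(
        seed=11,
        n_trials=12,
        baseline_rate_hz=10,
        theta_amp=0.008,
        noise_sd=0.004,
        phase_lock_kappa=2.0,
        hyperpol_prob=0.5,
        field="odorA",
        field_gain=3.0,
        loco_bout_rate_hz=0.2,
    )
    return generate_cell_session(cfg)
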