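"""Bayesian decoding of odor-specific time from single-cell spiking.

Time space is doubled by concatenating the cell's mean training-trial rate
over odor-A trials with that over odor-B trials (the "extended axis"): a
decoded bin in the first half means "that time point of an odor-A trial",
in the second half an odor-B trial.  At decoding step ``j`` the decoded bin
is

    argmax_t  K(t) * Poisson(s_j; tau * R_m(t)) * exp(-|t - T_prev|^2 / (2 sigma^2))

with ``tau`` the bin width (100 ms), ``K`` proportional to the training
odor proportions, and ``sigma`` = 3 s.  The continuity factor is applied
with a negative exponent (it "limits the decoded bin to a relative
proximity to the previous one") and is omitted at the first step; the
normalization constant does not affect the argmax and is not computed.
Ties break to the earliest bin.

Chance baselines come from decoding 500 circular-shift surrogates of each
decoded trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .io_model import CellSession, OdorDelayAxis
from .preprocess import bin_spike_counts, bin_rates

__all__ = [
    "IneligibleRecordingError",
    "DecoderModel",
    "DecodeResult",
    "fit_decoder",
    "decode_trial",
    "decode_counts_batch",
    "evaluate_decoding",
    "session_counts",
]

RATE_FLOOR_HZ = 1e-6
MIN_TRIALS = 10
MIN_TRAIN_PER_ODOR = 2
N_SURROGATES = 500
SIGMA_S = 3.0


class IneligibleRecordingError(Exception):
    """Session fails the trial-count eligibility rules."""


@dataclass
class DecoderModel:
    rates_hz: np.ndarray  # retained extended-axis template, floor-clamped
    log_prior: np.ndarray  # log K over retained bins
    retained_ext: np.ndarray  # original extended-bin index of each candidate
    n_bins: int  # bins per odor half
    tau_s: float
    sigma_s: float
    axis: OdorDelayAxis
    train_indices: np.ndarray
    test_indices: np.ndarray
    dropped_bins: np.ndarray  # within-trial bins dropped (no activity either odor)

    @property
    def ext_centers_s(self) -> np.ndarray:
        """Extended-axis bin centers (s) of the retained candidates."""
        return (self.retained_ext + 0.5) * self.tau_s


def session_counts(
    session: CellSession,
    axis: Optional[OdorDelayAxis] = None,
    smooth_points: int = 0,
) -> np.ndarray:
    """Spike counts per trial per axis bin (the decoder's input).

    With ``smooth_points`` > 1 the counts are five-point moving-average
    smoothed like the rates (decoded-trial activity is smoothed the same
    way as the training rates); the smoothed, non-integer counts enter the
    Poisson term through ``s * log(lam) - lam``, whose ``s!`` factor is a
    per-step constant and never affects the argmax.
    """
    axis = axis or OdorDelayAxis()
    counts = bin_spike_counts(session, axis)
    if smooth_points and smooth_points > 1:
        from .preprocess import moving_average

        return moving_average(counts, smooth_points, axis=1)
    return counts.astype(np.int64)


def fit_decoder(
    session: CellSession,
    axis: Optional[OdorDelayAxis] = None,
    smooth_points: int = 5,
    sigma_s: float = SIGMA_S,
) -> DecoderModel:
    """Build the concatenated two-odor rate template from the first
    two-thirds of trials (the final third is held out for decoding).

    Eligibility: at least 10 trials total and at least 2 training trials of
    each odor; per-trial rates are five-point smoothed and scaled so every
    trial's maximum equals the maximum over all trials.
    """
    axis = axis or OdorDelayAxis()
    n = session.n_trials
    if n < MIN_TRIALS:
        raise IneligibleRecordingError(f"need >= {MIN_TRIALS} trials, got {n}")
    n_train = (2 * n) // 3
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n)
    odors = np.array([t.odor1_id for t in session.trials])
    n_a = int(np.sum(odors[train_idx] == "A"))
    n_b = int(np.sum(odors[train_idx] == "B"))
    if n_a < MIN_TRAIN_PER_ODOR or n_b < MIN_TRAIN_PER_ODOR:
        raise IneligibleRecordingError(
            f"need >= {MIN_TRAIN_PER_ODOR} training trials per odor (A={n_a}, B={n_b})"
        )

    rates = bin_rates(session, axis, smooth_points=smooth_points).rates
    global_max = rates.max()
    scaled = rates.copy()
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        m = rates[i].max()
        if m > 0:
            scaled[i] *= global_max / m
        else:
            keep[i] = False  # zero-max trials excluded from the template

    tr_a = train_idx[(odors[train_idx] == "A") & keep[train_idx]]
    tr_b = train_idx[(odors[train_idx] == "B") & keep[train_idx]]
    mean_a = scaled[tr_a].mean(axis=0) if len(tr_a) else np.zeros(axis.n_bins)
    mean_b = scaled[tr_b].mean(axis=0) if len(tr_b) else np.zeros(axis.n_bins)
    template = np.concatenate([mean_a, mean_b])

    nb = axis.n_bins
    dropped_within = np.nonzero((mean_a == 0) & (mean_b == 0))[0]
    dropped_mask = np.zeros(2 * nb, dtype=bool)
    dropped_mask[dropped_within] = True
    dropped_mask[nb + dropped_within] = True
    retained_ext = np.nonzero(~dropped_mask)[0]
    if retained_ext.size == 0:
        raise IneligibleRecordingError("all bins dropped: no activity anywhere")

    prior = np.where(retained_ext < nb, n_a / (n_a + n_b), n_b / (n_a + n_b))
    prior = prior / prior.sum()

    return DecoderModel(
        rates_hz=np.maximum(template[retained_ext], RATE_FLOOR_HZ),
        log_prior=np.log(prior),
        retained_ext=retained_ext,
        n_bins=nb,
        tau_s=axis.bin_ms / 1000.0,
        sigma_s=sigma_s,
        axis=axis,
        train_indices=train_idx,
        test_indices=test_idx,
        dropped_bins=dropped_within,
    )


def decode_counts_batch(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """Decode many trials at once; ``counts`` is (trials, n_bins) integer
    spike counts.  Returns decoded extended-axis bin indices, same shape."""
    counts = np.atleast_2d(np.asarray(counts))
    m, nb = counts.shape
    if nb != model.n_bins:
        raise ValueError(f"expected {model.n_bins} bins per trial, got {nb}")
    lam = model.tau_s * model.rates_hz  # expected counts per candidate
    log_lam = np.log(lam)
    centers = model.ext_centers_s
    inv_two_sigma2 = 1.0 / (2.0 * model.sigma_s**2)

    decoded = np.empty((m, nb), dtype=np.int64)
    prev_t = np.zeros(m)  # seconds; unused at step 0
    for j in range(nb):
        # log posterior up to the per-step constant C
        logpost = model.log_prior + counts[:, j, None] * log_lam[None, :] - lam[None, :]
        if j > 0:
            logpost = logpost - ((centers[None, :] - prev_t[:, None]) ** 2) * inv_two_sigma2
        best = np.argmax(logpost, axis=1)  # earliest candidate on exact ties
        decoded[:, j] = model.retained_ext[best]
        prev_t = centers[best]
    return decoded


def decode_trial(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """Decoded extended-axis bin sequence for one trial's spike counts."""
    return decode_counts_batch(model, np.asarray(counts)[None, :])[0]


@dataclass
class DecodeResult:
    decoded: np.ndarray  # (trials, bins) extended-axis indices
    time_error_ms: float
    odor_accuracy: float
    chance_time_error_ms: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    chance_odor_accuracy: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


def _metrics(
    model: DecoderModel, decoded: np.ndarray, odor_ids: Sequence[str]
) -> tuple[float, float]:
    nb = model.n_bins
    bin_ms = model.axis.bin_ms
    j_centers = (np.arange(nb) + 0.5) * bin_ms
    within = decoded % nb
    decoded_ms = (within + 0.5) * bin_ms
    err = np.abs(decoded_ms - j_centers[None, :])
    first_half = decoded < nb
    is_a = np.asarray([o == "A" for o in odor_ids])
    correct = first_half == is_a[:, None]
    return float(err.mean()), float(correct.mean())


def evaluate_decoding(
    model: DecoderModel,
    counts: np.ndarray,
    odor_ids: Sequence[str],
    seed: int = 0,
    n_surrogates: int = N_SURROGATES,
) -> DecodeResult:
    """Decode held-out trials and score time error and odor accuracy
    against circular-shift chance distributions.

    Time error is the mean absolute within-trial distance (ms) between each
    time point and the decoded one, irrespective of odor; odor accuracy is
    the fraction of time steps decoded into the correct half of the
    extended axis.
    """
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] < 1:
        raise ValueError("need at least one decoded trial")
    decoded = decode_counts_batch(model, counts)
    time_error, accuracy = _metrics(model, decoded, odor_ids)

    rng = np.random.default_rng(seed)
    m, nb = counts.shape
    chance_err = np.empty(n_surrogates)
    chance_acc = np.empty(n_surrogates)
    col = np.arange(nb)
    # decode all surrogates in one batch per chunk to bound memory
    chunk = max(1, 20000 // max(m * nb, 1))
    s = 0
    while s < n_surrogates:
        c = min(chunk, n_surrogates - s)
        shifts = rng.integers(0, nb, size=(c, m))
        idx = (col[None, None, :] - shifts[:, :, None]) % nb
        surr = np.take_along_axis(np.broadcast_to(counts, (c, m, nb)), idx, axis=2)
        dec = decode_counts_batch(model, surr.reshape(c * m, nb)).reshape(c, m, nb)
        for k in range(c):
            chance_err[s + k], chance_acc[s + k] = _metrics(model, dec[k], odor_ids)
        s += c
    return DecodeResult(
        decoded=decoded,
        time_error_ms=time_error,
        odor_accuracy=accuracy,
        chance_time_error_ms=chance_err,
        chance_odor_accuracy=chance_acc,
    )
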