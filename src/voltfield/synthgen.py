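"""Synthetic session generator with known ground truth.

Produces :class:`~voltfield.io_model.CellSession` objects whose traces carry
the statistical structure the downstream analyses assume: a theta-band
subthreshold oscillation with configurable spike phase locking, odor-locked
firing fields, odor-onset hyperpolarization dips with optional theta phase
reset, fast onset/rebound spiking envelopes, photobleaching drift and
locomotion bouts.  Every injected event is recorded in a
:class:`GroundTruth` so recovery can be scored exactly.

Spikes are drawn from an inhomogeneous Poisson process (per-ms Bernoulli
thinning with a 2-ms refractory period) whose rate is

    baseline x field bump x von-Mises theta modulation x onset/rebound gain.

The subthreshold trace is pink (1/f) noise plus a sinusoidal theta whose
amplitude follows an Ornstein-Uhlenbeck jitter; spike waveforms
(difference-of-exponentials with an after-hyperpolarization lobe) are added
linearly.  All randomness comes from one ``numpy`` Generator seeded by
``SynthConfig.seed``, with draws in a fixed documented order, so equal seeds
give identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter
from scipy.special import i0

from .io_model import (
    CellSession,
    TrialRecord,
    ODOR1_ONSET_MS,
    ODOR_DURATION_MS,
    DELAY_MS,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "EphysUnit",
    "EphysSession",
    "generate_cell_session",
    "generate_multiday_ensemble",
    "generate_ephys_session",
]

FIELD_KINDS = ("none", "odorA", "odorB", "both", "delay")


@dataclass
class SynthConfig:
    """Generator parameters; defaults follow the population summaries that
    motivated them (hyperpolarization onset ~20 ms, duration ~190 ms,
    onset/rebound windows 20-50 ms and 200-500 ms post-odor)."""

    seed: int = 0
    n_trials: int = 20
    trial_len_ms: int = 11000

    # spiking
    baseline_rate_hz: float = 10.0
    refractory_ms: int = 2

    # subthreshold theta
    theta_freq_hz: float = 7.0
    theta_amp: float = 0.01
    theta_amp_jitter: float = 0.2  # OU jitter, fraction of theta_amp
    phase_lock_kappa: float = 0.0
    preferred_phase_rad: float = 0.0

    # firing field
    field: str = "none"  # none | odorA | odorB | both | delay
    field_center_ms: float = 300.0  # relative to odor1 onset
    field_width_ms: float = 500.0  # FWHM of the Gaussian bump
    field_gain: float = 3.0  # bump height over baseline: peak = baseline * (1 + gain)

    # odor-onset hyperpolarization
    hyperpol_prob: float = 0.0
    hyperpol_onset_ms: float = 20.0
    hyperpol_onset_jitter_ms: float = 0.0
    hyperpol_amplitude_sd: float = -4.5
    hyperpol_amplitude_jitter_sd: float = 0.0
    hyperpol_duration_ms: float = 190.0
    hyperpol_duration_jitter_ms: float = 0.0
    hyperpol_ramp_ms: float = 5.0
    reset_phase_rad: Optional[float] = None

    # fine-timescale spiking envelopes
    onset_burst_prob: float = 0.0
    onset_burst_gain: float = 8.0
    onset_burst_window: tuple[float, float] = (20.0, 50.0)
    rebound_gain: float = 1.0
    rebound_window: tuple[float, float] = (200.0, 500.0)

    # spike waveform (added to dff)
    spike_amp: float = 0.05
    spike_halfwidth_ms: float = 1.5
    spike_ahp_frac: float = 0.3

    # trace composition
    noise_sd: float = 0.005
    bleach_tau_s: float = 60.0
    bleach_amp: float = 0.0
    synth_dff: bool = True  # False skips trace synthesis (spikes only)

    # locomotion
    loco_bout_rate_hz: float = 0.1
    loco_bout_dur_ms: float = 800.0
    loco_amp: float = 0.05
    loco_odor_boost: float = 1.0

    # multiday
    n_sessions: int = 1
    retention_prob: float = 1.0
    field_redraw_prob: float = 0.0  # P(field present) when status is redrawn
    training_switch_session: int = 1

    # ephys
    n_units: int = 40
    frac_narrow: float = 0.2
    class_separation: float = 6.0
    frac_inhibited: float = 0.7
    lfp_fs: float = 2500.0
    lfp_duration_s: float = 60.0
    n_ripples: int = 0
    ripple_amplitude_sd: float = 12.0
    ripple_duration_ms: float = 80.0
    ripple_freq_hz: float = 150.0

    # identity
    cell_id: str = "synth-0"
    mouse_id: str = "m0"
    cell_class: str = "PV"
    training_state: str = "trained"
    session_index: int = 0

    def validate(self) -> None:
        for name in (
            "hyperpol_prob",
            "onset_burst_prob",
            "retention_prob",
            "field_redraw_prob",
            "frac_narrow",
            "frac_inhibited",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.field not in FIELD_KINDS:
            raise ValueError(f"field must be one of {FIELD_KINDS}")
        if self.field_width_ms <= 0 or self.hyperpol_duration_ms <= 0:
            raise ValueError("widths/durations must be positive")
        if self.phase_lock_kappa < 0:
            raise ValueError("phase_lock_kappa must be >= 0")
        if self.n_trials < 1 or self.trial_len_ms < 2000:
            raise ValueError("need >= 1 trial of >= 2000 ms")
        if self.baseline_rate_hz < 0 or self.noise_sd < 0 or self.theta_amp < 0:
            raise ValueError("rates/amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Everything injected into one generated session."""

    field: str
    field_center_ms: float
    field_width_ms: float
    field_gain: float
    odor1_ids: list[str] = dc_field(default_factory=list)
    rate_hz: list[np.ndarray] = dc_field(default_factory=list)  # per-ms, per trial
    subthreshold: list[np.ndarray] = dc_field(default_factory=list)
    theta_phase: list[np.ndarray] = dc_field(default_factory=list)
    spike_times: list[np.ndarray] = dc_field(default_factory=list)
    # (trial, onset_ms rel. odor1, duration_ms, depth_sd, trough_ms rel. odor1)
    hyperpol_events: list[tuple[int, float, float, float, float]] = dc_field(
        default_factory=list
    )
    # dip depth actually added, in dff units and in smoothed-baseline s.d.
    # units, parallel to hyperpol_events
    hyperpol_depths: list[tuple[float, float]] = dc_field(default_factory=list)
    onset_burst_trials: list[int] = dc_field(default_factory=list)

    @property
    def has_field(self) -> bool:
        return self.field != "none"

    @property
    def has_odor_field(self) -> bool:
        return self.field != "none" and self.field_center_ms < ODOR_DURATION_MS


@dataclass
class EphysUnit:
    peak_trough_ms: float
    peak_trough_ratio: float
    mean_rate_hz: float
    true_class: str  # broad | narrow
    odor_sign: Optional[str]  # excited | inhibited | None
    spike_trains: list[np.ndarray]  # per trial, ms from trial start


@dataclass
class EphysSession:
    units: list[EphysUnit]
    lfp: np.ndarray
    lfp_fs: float
    ripple_intervals: list[tuple[float, float]]  # ms
    n_trials: int
    trial_len_ms: int


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_kernel(cfg: SynthConfig) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials waveform; returns (kernel, peak index)."""
    tau_r = max(cfg.spike_halfwidth_ms / 3.0, 0.2)
    tau_d = max(cfg.spike_halfwidth_ms, 0.5)
    t = np.arange(0, 20.0, 1.0)
    w = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = int(np.argmax(w))
    if w[peak] > 0:
        w = w / w[peak] * cfg.spike_amp
    # after-hyperpolarization lobe starting just past the peak
    ahp = -cfg.spike_ahp_frac * cfg.spike_amp * np.exp(-(t - peak - 2) / 5.0)
    ahp[: peak + 2] = 0.0
    return w + ahp, peak


def _ou_series(rng: np.random.Generator, n: int, tau_ms: float = 500.0) -> np.ndarray:
    from scipy.signal import lfilter

    a = np.exp(-1.0 / tau_ms)
    innov = rng.standard_normal(n) * np.sqrt(1 - a * a)
    innov[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -a], innov)


def _draw_spikes(rng: np.random.Generator, rate_hz: np.ndarray, refractory_ms: int) -> np.ndarray:
    p = np.clip(rate_hz / 1000.0, 0.0, 0.95)
    hits = np.nonzero(rng.random(len(p)) < p)[0]
    if hits.size == 0:
        return hits.astype(np.int64)
    keep = [int(hits[0])]
    for t in hits[1:]:
        if t - keep[-1] > refractory_ms:
            keep.append(int(t))
    return np.asarray(keep, dtype=np.int64)


def _field_bump(cfg: SynthConfig, t_ms: np.ndarray, odor1: str) -> np.ndarray:
    """Multiplicative rate envelope for the configured field spec."""
    applies = (
        cfg.field == "both"
        or cfg.field == "delay"
        or (cfg.field == "odorA" and odor1 == "A")
        or (cfg.field == "odorB" and odor1 == "B")
    )
    if cfg.field == "none" or not applies:
        return np.ones_like(t_ms, dtype=float)
    center = ODOR1_ONSET_MS + cfg.field_center_ms
    sigma = cfg.field_width_ms / 2.355  # FWHM -> sd
    return 1.0 + cfg.field_gain * np.exp(-((t_ms - center) ** 2) / (2 * sigma**2))


def _hyperpol_dip_shape(duration: float, ramp: float, n: int, start: int) -> np.ndarray:
    """Unit-depth trapezoid dip (Tukey-like ramps) starting at ``start``."""
    dur = int(round(duration))
    ramp = min(ramp, duration / 2.0)
    t = np.arange(dur, dtype=float)
    shape = np.ones(dur)
    r = max(int(round(ramp)), 1)
    up = np.linspace(0, 1, r, endpoint=False)
    shape[:r] = up
    shape[dur - r:] = up[::-1]
    out = np.zeros(n)
    lo = max(start, 0)
    hi = min(start + dur, n)
    if hi > lo:
        out[lo:hi] = shape[lo - start: hi - start]
    return out


def generate_cell_session(cfg: SynthConfig) -> tuple[CellSession, GroundTruth]:
    """Generate one synthetic session and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gt = GroundTruth(
        field=cfg.field,
        field_center_ms=cfg.field_center_ms,
        field_width_ms=cfg.field_width_ms,
        field_gain=cfg.field_gain,
    )
    trials = _generate_trials(cfg, rng, gt)
    session = CellSession(
        cell_id=cfg.cell_id,
        mouse_id=cfg.mouse_id,
        cell_class=cfg.cell_class,
        training_state=cfg.training_state,
        session_index=cfg.session_index,
        sample_rate=1000.0,
        trials=trials,
    )
    session.validate()
    return session, gt


def _generate_trials(
    cfg: SynthConfig, rng: np.random.Generator, gt: GroundTruth
) -> list[TrialRecord]:
    n = cfg.trial_len_ms
    t_ms = np.arange(n, dtype=float)
    kernel, kpeak = _spike_kernel(cfg)
    onset = ODOR1_ONSET_MS
    odor1_off = onset + ODOR_DURATION_MS
    odor2_on = odor1_off + DELAY_MS
    odor2_off = odor2_on + ODOR_DURATION_MS
    kappa = cfg.phase_lock_kappa
    vm_norm = i0(kappa)
    trials: list[TrialRecord] = []

    for k in range(cfg.n_trials):
        odor1 = "A" if rng.random() < 0.5 else "B"
        odor2 = "A" if rng.random() < 0.5 else "B"

        # -- theta oscillator phase --------------------------------------
        phi0 = rng.uniform(-np.pi, np.pi)
        phase = 2 * np.pi * cfg.theta_freq_hz * t_ms / 1000.0 + phi0

        # -- hyperpolarization draw (phase reset needs it first) ---------
        hyp = None
        if cfg.hyperpol_prob > 0 and rng.random() < cfg.hyperpol_prob:
            h_on = max(0.0, cfg.hyperpol_onset_ms + cfg.hyperpol_onset_jitter_ms * rng.standard_normal())
            h_dur = max(
                40.0,
                cfg.hyperpol_duration_ms + cfg.hyperpol_duration_jitter_ms * rng.standard_normal(),
            )
            h_amp = min(
                -1.0,
                cfg.hyperpol_amplitude_sd + cfg.hyperpol_amplitude_jitter_sd * rng.standard_normal(),
            )
            hyp = (h_on, h_dur, h_amp)
            if cfg.reset_phase_rad is not None:
                trough = int(onset + h_on + h_dur / 2.0)
                if trough < n:
                    # snap oscillator phase at the trough, keep frequency
                    phase[trough:] += cfg.reset_phase_rad - phase[trough]

        wrapped = np.angle(np.exp(1j * phase))

        # -- rate function -------------------------------------------------
        rate = np.full(n, cfg.baseline_rate_hz, dtype=float)
        rate *= _field_bump(cfg, t_ms, odor1)
        if kappa > 0:
            rate *= np.exp(kappa * np.cos(wrapped - cfg.preferred_phase_rad)) / vm_norm
        burst_drawn = cfg.onset_burst_prob > 0 and rng.random() < cfg.onset_burst_prob
        if burst_drawn:
            w0, w1 = cfg.onset_burst_window
            rate[int(onset + w0): int(onset + w1)] *= cfg.onset_burst_gain
            gt.onset_burst_trials.append(k)
        if cfg.rebound_gain != 1.0:
            r0, r1 = cfg.rebound_window
            rate[int(onset + r0): int(onset + r1)] *= cfg.rebound_gain

        spikes = _draw_spikes(rng, rate, cfg.refractory_ms)

        # -- subthreshold trace -------------------------------------------
        if cfg.synth_dff:
            amp_jit = 1.0 + cfg.theta_amp_jitter * _ou_series(rng, n)
            theta = cfg.theta_amp * np.clip(amp_jit, 0.1, None) * np.sin(phase)
            noise = cfg.noise_sd * _pink_noise(rng, n)
            bleach = cfg.bleach_amp * (np.exp(-t_ms / (1000.0 * cfg.bleach_tau_s)) - 1.0)
            sub = theta + noise + bleach
            if hyp is not None:
                h_on, h_dur, h_amp = hyp
                base = savgol_filter(sub, 21, 1)[onset - 500: onset]
                base_sd = float(base.std())
                depth = abs(h_amp) * base_sd
                dip = _hyperpol_dip_shape(h_dur, cfg.hyperpol_ramp_ms, n, int(onset + h_on))
                sub = sub - depth * dip
                gt.hyperpol_events.append(
                    (k, h_on, h_dur, h_amp, h_on + h_dur / 2.0)
                )
                gt.hyperpol_depths.append((depth, depth / base_sd if base_sd > 0 else 0.0))
            dff = sub.copy()
            for s in spikes:
                lo = s - kpeak
                hi = lo + len(kernel)
                klo = max(0, -lo)
                khi = len(kernel) - max(0, hi - n)
                dff[max(lo, 0): min(hi, n)] += kernel[klo:khi]
        else:
            sub = np.zeros(n)
            dff = np.zeros(n)
            if hyp is not None:
                gt.hyperpol_events.append((k, hyp[0], hyp[1], hyp[2], hyp[0] + hyp[1] / 2.0))
                gt.hyperpol_depths.append((0.0, 0.0))  # no trace synthesized

        # -- locomotion ----------------------------------------------------
        loco = np.zeros(n)
        n_bouts = rng.poisson(cfg.loco_bout_rate_hz * n / 1000.0)
        for _ in range(n_bouts):
            b0 = int(rng.uniform(0, n))
            b1 = min(n, b0 + int(cfg.loco_bout_dur_ms))
            loco[b0:b1] = cfg.loco_amp * (1.0 + 0.2 * rng.standard_normal())
        if cfg.loco_odor_boost != 1.0:
            loco[onset:odor1_off] *= cfg.loco_odor_boost
            loco[odor2_on:odor2_off] *= cfg.loco_odor_boost

        gt.odor1_ids.append(odor1)
        gt.rate_hz.append(rate)
        gt.subthreshold.append(sub)
        gt.theta_phase.append(wrapped)
        gt.spike_times.append(spikes)
        trials.append(
            TrialRecord(
                dff=dff,
                spike_times=spikes,
                locomotion=loco,
                odor1_id=odor1,
                odor2_id=odor2,
                response_window_end=min(11000, n),
            )
        )
    return trials


def generate_multiday_ensemble(cfg: SynthConfig) -> list[tuple[CellSession, GroundTruth]]:
    """Generate one cell tracked over ``cfg.n_sessions`` days.

    The field specification carries over from day ``d`` to ``d + 1`` with
    probability ``retention_prob``; otherwise field status is redrawn
    (present with probability ``field_redraw_prob``, at a fresh odor and
    center).  ``training_state`` flips at ``training_switch_session``.
    """
    cfg.validate()
    if cfg.n_sessions < 2:
        raise ValueError("multiday ensemble needs n_sessions >= 2")
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[CellSession, GroundTruth]] = []
    spec = (cfg.field, cfg.field_center_ms)
    for d in range(cfg.n_sessions):
        if d > 0 and rng.random() >= cfg.retention_prob:
            if rng.random() < cfg.field_redraw_prob:
                new_field = "odorA" if rng.random() < 0.5 else "odorB"
                new_center = float(rng.uniform(0, ODOR_DURATION_MS))
                spec = (new_field, new_center)
            else:
                spec = ("none", cfg.field_center_ms)
        day_cfg = dataclasses.replace(
            cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
            field=spec[0],
            field_center_ms=spec[1],
            session_index=d,
            training_state="trained" if d >= cfg.training_switch_session else "naive",
            n_sessions=1,
        )
        out.append(generate_cell_session(day_cfg))
    return out


def generate_ephys_session(cfg: SynthConfig) -> EphysSession:
    """Generate extracellular units, waveform features and an LFP trace.

    Two unit classes with feature distributions separated by
    ``class_separation`` (Mahalanobis-style, in pooled-s.d. units per
    feature axis); pyramidal (broad) units get odor-excited or
    odor-inhibited rate modulation; the LFP is 1/f noise with
    ``n_ripples`` injected 120-200 Hz bursts at known times.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- unit features ---------------------------------------------------
    # per-feature means sit +/- sep/2 pooled s.d. from a common midpoint
    sds = np.array([0.1, 0.08, 1.0])  # peak-trough ms, ratio, rate Hz
    mid = np.array([0.55, 0.45, 4.0])
    off = cfg.class_separation / 2.0 / np.sqrt(3.0)  # split across 3 axes
    broad_mu = mid + off * sds * np.array([1.0, 1.0, -1.0])
    narrow_mu = mid - off * sds * np.array([1.0, 1.0, -1.0])

    units: list[EphysUnit] = []
    for _ in range(cfg.n_units):
        narrow = rng.random() < cfg.frac_narrow
        mu = narrow_mu if narrow else broad_mu
        feats = mu + sds * rng.standard_normal(3)
        base_rate = max(float(feats[2]), 0.6)
        odor_sign = None
        if not narrow:
            odor_sign = "inhibited" if rng.random() < cfg.frac_inhibited else "excited"
        trains = []
        for _k in range(cfg.n_trials):
            rate = np.full(cfg.trial_len_ms, base_rate)
            if odor_sign == "excited":
                rate[ODOR1_ONSET_MS: ODOR1_ONSET_MS + ODOR_DURATION_MS] *= 3.0
            elif odor_sign == "inhibited":
                rate[ODOR1_ONSET_MS: ODOR1_ONSET_MS + ODOR_DURATION_MS] *= 0.25
            trains.append(_draw_spikes(rng, rate, cfg.refractory_ms))
        units.append(
            EphysUnit(
                peak_trough_ms=float(feats[0]),
                peak_trough_ratio=float(feats[1]),
                mean_rate_hz=base_rate,
                true_class="narrow" if narrow else "broad",
                odor_sign=odor_sign,
                spike_trains=trains,
            )
        )

    # ---- LFP with injected ripples --------------------------------------
    n_lfp = int(cfg.lfp_duration_s * cfg.lfp_fs)
    lfp = _pink_noise(rng, n_lfp) * 50.0  # arbitrary uV-ish scale
    ripple_intervals: list[tuple[float, float]] = []
    if cfg.n_ripples > 0:
        from scipy.signal import butter, filtfilt

        b, a = butter(3, [120.0, 200.0], btype="bandpass", fs=cfg.lfp_fs)
        band = filtfilt(b, a, lfp)
        bin_n = int(0.010 * cfg.lfp_fs)
        nb = len(band) // bin_n
        rms = np.sqrt(np.mean(band[: nb * bin_n].reshape(nb, bin_n) ** 2, axis=1))
        mu, sd = float(rms.mean()), float(rms.std())
        target_rms = mu + cfg.ripple_amplitude_sd * sd
        amp = np.sqrt(2.0) * target_rms  # sine RMS = amp / sqrt(2)

        dur_n = int(cfg.ripple_duration_ms / 1000.0 * cfg.lfp_fs)
        margin = int(0.2 * cfg.lfp_fs)
        slots = np.sort(
            rng.choice(
                np.arange(margin, n_lfp - dur_n - margin, 3 * dur_n),
                size=cfg.n_ripples,
                replace=False,
            )
        )
        tt = np.arange(dur_n) / cfg.lfp_fs
        env = np.sin(np.pi * np.arange(dur_n) / dur_n) ** 0.5  # soft edges
        for s0 in slots:
            tone = amp * env * np.sin(2 * np.pi * cfg.ripple_freq_hz * tt + rng.uniform(0, 2 * np.pi))
            lfp[s0: s0 + dur_n] += tone
            ripple_intervals.append(
                (s0 / cfg.lfp_fs * 1000.0, (s0 + dur_n) / cfg.lfp_fs * 1000.0)
            )

    return EphysSession(
        units=units,
        lfp=lfp,
        lfp_fs=cfg.lfp_fs,
        ripple_intervals=ripple_intervals,
        n_trials=cfg.n_trials,
        trial_len_ms=cfg.trial_len_ms,
    )
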