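"""Per-trial signal conditioning and basic spiking/subthreshold metrics.

Covers motion segmentation, firing-rate binning, burst index, speed and odor
scores, spike-waveform removal (de-spiking), spectra/spectrograms, theta
phase/amplitude extraction and circular spike-phase statistics.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.signal import butter, filtfilt, hilbert, savgol_filter

from .io_model import CellSession, OdorDelayAxis, TrialRecord

__all__ = [
    "MotionSegments",
    "RateMatrix",
    "ThetaSignal",
    "SpikePhaseStats",
    "segment_motion",
    "bin_rates",
    "bin_spike_counts",
    "burst_index",
    "speed_score",
    "odor_score",
    "despike",
    "power_spectrum",
    "spectrogram_flattened",
    "theta_extract",
    "spike_phase_stats",
]

THETA_BAND = (4.0, 10.0)
SAVGOL_WINDOW = 21  # samples at 1 kHz; polyorder 1 throughout


@dataclass
class MotionSegments:
    segments: list[tuple[int, int]]  # [start, end) ms, motion
    immobility: list[tuple[int, int]]
    n_samples: int


@dataclass
class RateMatrix:
    rates: np.ndarray  # trials x bins, Hz (or z-units if z-scored)
    axis: OdorDelayAxis
    smoothing: str


@dataclass
class ThetaSignal:
    phase: np.ndarray  # rad in (-pi, pi], per ms
    amplitude: np.ndarray  # >= 0, per ms
    band: tuple[float, float] = THETA_BAND


@dataclass
class SpikePhaseStats:
    preferred_phase: float
    vector_length: float
    n_spikes: int


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def segment_motion(
    locomotion: np.ndarray,
    enter_threshold: float = 0.02,
    exit_threshold: float = 0.01,
    merge_gap_ms: int = 20,
    min_duration_ms: int = 10,
    savgol_window: int = SAVGOL_WINDOW,
) -> MotionSegments:
    """Hysteresis-threshold motion bouts from the 1 kHz locomotion signal.

    The signal is mode-subtracted, rectified and Savitzky-Golay smoothed;
    motion starts when it exceeds ``enter_threshold`` and ends when it drops
    below ``exit_threshold``.  Bouts closer than ``merge_gap_ms`` are
    concatenated and bouts shorter than ``min_duration_ms`` discarded.
    """
    x = np.asarray(locomotion, dtype=float)
    if x.size == 0:
        raise ValueError("empty locomotion signal")
    vals, counts = np.unique(np.round(x, 6), return_counts=True)
    mode = vals[np.argmax(counts)]
    y = np.abs(x - mode)
    if len(y) > savgol_window:
        y = savgol_filter(y, savgol_window, 1)

    segments: list[tuple[int, int]] = []
    in_motion = False
    start = 0
    for i, v in enumerate(y):
        if not in_motion and v > enter_threshold:
            in_motion, start = True, i
        elif in_motion and v < exit_threshold:
            segments.append((start, i))
            in_motion = False
    if in_motion:
        segments.append((start, len(y)))

    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] < merge_gap_ms:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    kept = [s for s in merged if s[1] - s[0] >= min_duration_ms]

    immobility: list[tuple[int, int]] = []
    prev = 0
    for s0, s1 in kept:
        if s0 > prev:
            immobility.append((prev, s0))
        prev = s1
    if prev < len(y):
        immobility.append((prev, len(y)))
    return MotionSegments(segments=kept, immobility=immobility, n_samples=len(y))


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, span: int, axis: int = -1) -> np.ndarray:
    """Centered moving average with shrinking edge windows (movmean-style):
    edge bins average only the available points, so no zero-pad bias."""
    if span <= 1:
        return np.asarray(x, dtype=float)
    kern = np.ones(span)

    def _ma(v: np.ndarray) -> np.ndarray:
        num = np.convolve(v, kern, mode="same")
        den = np.convolve(np.ones_like(v), kern, mode="same")
        return num / den

    return np.apply_along_axis(_ma, axis, np.asarray(x, dtype=float))


def bin_spike_counts(session: CellSession, axis: OdorDelayAxis) -> np.ndarray:
    """Raw per-trial spike counts on the axis bins (trials x bins)."""
    edges = axis.edges
    counts = np.zeros((session.n_trials, axis.n_bins))
    for i, tr in enumerate(session.trials):
        if axis.end_ms > tr.n_samples:
            raise ValueError("axis extends past trial end")
        counts[i], _ = np.histogram(tr.spike_times, bins=edges)
    return counts


def bin_rates(
    session: CellSession,
    axis: OdorDelayAxis,
    smooth_points: int = 0,
    zscore: bool = False,
) -> RateMatrix:
    """Per-trial binned firing rates (Hz), optionally moving-average smoothed
    over ``smooth_points`` bins and z-scored per trial over the axis."""
    rates = bin_spike_counts(session, axis) / (axis.bin_ms / 1000.0)
    desc = "none"
    if smooth_points and smooth_points > 1:
        rates = moving_average(rates, smooth_points, axis=1)
        desc = f"ma{smooth_points}"
    if zscore:
        mu = rates.mean(axis=1, keepdims=True)
        sd = rates.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        rates = (rates - mu) / sd
        desc += "+z"
    return RateMatrix(rates=rates, axis=axis, smoothing=desc)


def burst_index(spike_times: np.ndarray) -> Optional[float]:
    """Fraction of spikes with an inter-spike interval < 10 ms.

    Counts ISIs below 10 ms over the total number of spikes; undefined
    (None) below two spikes.
    """
    st = np.asarray(spike_times)
    if st.size < 2:
        return None
    isi = np.diff(st)
    return float(np.sum(isi < 10) / st.size)


def _trial_scores(
    session: CellSession,
    target_fn,
    bin_ms: int = 100,
    smooth_points: int = 5,
) -> list[float]:
    scores = []
    for tr in session.trials:
        n_bins = tr.n_samples // bin_ms
        edges = np.arange(0, (n_bins + 1) * bin_ms, bin_ms)
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        rate = moving_average(counts / (bin_ms / 1000.0), smooth_points)
        target = target_fn(tr, n_bins, bin_ms)
        if rate.std() == 0 or target.std() == 0:
            warnings.warn("constant vector in trial; correlation undefined, excluded")
            continue
        scores.append(float(np.corrcoef(rate, target)[0, 1]))
    return scores


def _chance_band(
    session: CellSession,
    target_fn,
    seed: int,
    n_surrogates: int = 1000,
    bin_ms: int = 100,
    smooth_points: int = 5,
) -> tuple[float, float]:
    """2.5/97.5 percentile band of circular-shift surrogate mean scores."""
    rng = np.random.default_rng(seed)
    per_trial = []
    for tr in session.trials:
        n_bins = tr.n_samples // bin_ms
        edges = np.arange(0, (n_bins + 1) * bin_ms, bin_ms)
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        rate = moving_average(counts / (bin_ms / 1000.0), smooth_points)
        target = target_fn(tr, n_bins, bin_ms)
        if rate.std() == 0 or target.std() == 0:
            continue
        per_trial.append((rate, target))
    if not per_trial:
        return (np.nan, np.nan)
    means = np.empty(n_surrogates)
    for s in range(n_surrogates):
        vals = []
        for rate, target in per_trial:
            shift = int(rng.integers(0, len(rate)))
            vals.append(np.corrcoef(np.roll(rate, shift), target)[0, 1])
        means[s] = np.mean(vals)
    return (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))


def speed_score(
    session: CellSession,
    seed: int = 0,
    n_surrogates: int = 1000,
    smooth_points: int = 5,
) -> tuple[float, tuple[float, float]]:
    """Trial-averaged Pearson correlation of smoothed 100-ms rates with the
    bin-averaged locomotion signal, plus a circular-shift chance band."""

    def target(tr: TrialRecord, n_bins: int, bin_ms: int) -> np.ndarray:
        return tr.locomotion[: n_bins * bin_ms].reshape(n_bins, bin_ms).mean(axis=1)

    scores = _trial_scores(session, target, smooth_points=smooth_points)
    mean = float(np.mean(scores)) if scores else np.nan
    return mean, _chance_band(session, target, seed, n_surrogates, smooth_points=smooth_points)


def odor_score(
    session: CellSession,
    seed: int = 0,
    n_surrogates: int = 1000,
    smooth_points: int = 5,
) -> tuple[float, tuple[float, float]]:
    """Trial-averaged correlation of rates with the odor-delivery boxcar."""

    def target(tr: TrialRecord, n_bins: int, bin_ms: int) -> np.ndarray:
        box = np.zeros(n_bins)
        for a, b in ((tr.odor1_onset, tr.odor1_offset), (tr.odor2_onset, tr.odor2_offset)):
            box[a // bin_ms: b // bin_ms] = 1.0
        return box

    scores = _trial_scores(session, target, smooth_points=smooth_points)
    mean = float(np.mean(scores)) if scores else np.nan
    return mean, _chance_band(session, target, seed, n_surrogates, smooth_points=smooth_points)


# ---------------------------------------------------------------------------
# de-spiking
# ---------------------------------------------------------------------------

def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for w in sorted(windows):
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


def _yule_walker_ar2(x: np.ndarray) -> tuple[np.ndarray, float]:
    """AR(2) coefficients and innovation variance from autocovariances."""
    x = x - x.mean()
    n = len(x)
    if n < 8 or x.std() == 0:
        return np.zeros(2), float(np.var(x))
    c = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(3)])
    R = np.array([[c[0], c[1]], [c[1], c[0]]])
    try:
        phi = np.linalg.solve(R, c[1:])
    except np.linalg.LinAlgError:
        return np.zeros(2), float(c[0])
    sigma2 = max(c[0] - phi @ c[1:], 1e-18)
    # keep the generator stable
    if np.any(np.abs(np.roots([1, -phi[0], -phi[1]])) >= 0.999):
        phi *= 0.98
    return phi, float(sigma2)


def despike(
    dff: np.ndarray,
    spike_times: np.ndarray,
    pre_ms: int = 5,
    post_ms: int = 19,
    flank_ms: int = 50,
) -> np.ndarray:
    """Replace a 25-ms window around each spike (5 ms before to 19 ms after
    the peak) by a boundary-matched surrogate.

    The surrogate is a linear interpolation between the window-boundary
    samples plus noise whose spectrum matches an AR(2) fit of the detrended
    flanking ``flank_ms`` on each side.  The noise stream is seeded from the
    flank content, so the operation is idempotent and deterministic;
    samples outside the windows are untouched.  Overlapping windows are
    merged, never double-replaced.
    """
    x = np.asarray(dff, dtype=float).copy()
    n = len(x)
    if len(spike_times) == 0:
        return x
    windows = _merge_windows(
        [(max(int(s) - pre_ms, 0), min(int(s) + post_ms + 1, n)) for s in spike_times]
    )
    for w0, w1 in windows:
        left = x[max(w0 - flank_ms, 0): w0]
        right = x[w1: min(w1 + flank_ms, n)]
        flank = np.concatenate([left, right])
        a = x[w0 - 1] if w0 > 0 else (flank[0] if flank.size else 0.0)
        b = x[w1] if w1 < n else (flank[-1] if flank.size else 0.0)
        m = w1 - w0
        interp = a + (b - a) * (np.arange(1, m + 1) / (m + 1))
        if flank.size >= 16:
            detr = signal.detrend(flank)
            phi, sigma2 = _yule_walker_ar2(detr)
            seed = zlib.crc32(flank.tobytes()) ^ zlib.crc32(str(w0).encode())
            rng = np.random.default_rng(seed)
            innov = rng.standard_normal(m + 20) * np.sqrt(sigma2)
            ar = signal.lfilter([1.0], np.concatenate([[1.0], -phi]), innov)[20:]
            taper = np.ones(m)
            ramp = min(3, m // 2)
            if ramp > 0:
                taper[:ramp] = np.linspace(0, 1, ramp + 1)[1:]
                taper[m - ramp:] = np.linspace(1, 0, ramp + 1)[:-1]
            interp = interp + ar * taper
        x[w0:w1] = interp
    return x


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def power_spectrum(
    segments: Sequence[np.ndarray],
    fs: float = 1000.0,
    freq_resolution_hz: float = 0.5,
    kaiser_beta: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified periodogram (Kaiser window) of concatenated segments at the
    requested frequency resolution (zero-padded as needed)."""
    segs = [np.asarray(s, dtype=float) for s in segments if len(s) > 0]
    if not segs:
        raise ValueError("no segments")
    x = np.concatenate(segs)
    nfft = max(len(x), int(round(fs / freq_resolution_hz)))
    freqs, power = signal.periodogram(
        x, fs=fs, window=("kaiser", kaiser_beta), nfft=nfft, detrend="constant"
    )
    return freqs, power


def spectrogram_flattened(
    trace: np.ndarray,
    fs: float = 1000.0,
    window_ms: int = 512,
    overlap_ms: int = 256,
    gaussian_sigma: float = 5.0,
    fit_band_hz: tuple[float, float] = (1.0, 100.0),
    zoom: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time spectrogram, 2-D interpolated, Gaussian-smoothed, and
    flattened by removing a fitted 1/f^a power law.

    Returns ``(times_s, freqs_hz, matrix)`` with matrix shaped
    (freqs, times).
    """
    from scipy import ndimage

    x = np.asarray(trace, dtype=float)
    nper = int(window_ms * fs / 1000.0)
    if len(x) < nper:
        raise ValueError("trace shorter than one spectrogram window")
    nover = int(overlap_ms * fs / 1000.0)
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, nperseg=nper, noverlap=nover, detrend="constant"
    )
    if zoom > 1:
        sxx = ndimage.zoom(sxx, zoom, order=1)
        freqs = np.linspace(freqs[0], freqs[-1], sxx.shape[0])
        times = np.linspace(times[0], times[-1], sxx.shape[1])
    sxx = ndimage.gaussian_filter(sxx, sigma=gaussian_sigma)

    mean_spec = sxx.mean(axis=1)
    band = (freqs >= fit_band_hz[0]) & (freqs <= fit_band_hz[1]) & (mean_spec > 0)
    if band.sum() >= 2:
        lf = np.log10(freqs[band])
        lp = np.log10(mean_spec[band])
        slope, intercept = np.polyfit(lf, lp, 1)
        with np.errstate(divide="ignore"):
            model = 10.0 ** (intercept + slope * np.log10(np.maximum(freqs, freqs[band][0])))
        sxx = sxx / model[:, None]
    return times, freqs, sxx


# ---------------------------------------------------------------------------
# theta
# ---------------------------------------------------------------------------

def theta_extract(
    despiked_dff: np.ndarray,
    fs: float = 1000.0,
    band: tuple[float, float] = THETA_BAND,
    savgol_window: int = SAVGOL_WINDOW,
) -> ThetaSignal:
    """Theta phase/amplitude from the analytic signal of the bandpassed
    (zero-phase 3rd-order Butterworth, 4-10 Hz) de-spiked trace."""
    x = np.asarray(despiked_dff, dtype=float)
    if len(x) < int(3 * fs / band[0]):
        raise ValueError("trace too short for theta extraction")
    b, a = butter(3, band, btype="bandpass", fs=fs)
    filtered = filtfilt(b, a, x)
    analytic = hilbert(filtered)
    phase = np.angle(analytic)
    amplitude = np.abs(analytic)
    if len(amplitude) > savgol_window:
        amplitude = np.clip(savgol_filter(amplitude, savgol_window, 1), 0.0, None)
    return ThetaSignal(phase=phase, amplitude=amplitude, band=band)


def spike_phase_stats(theta: ThetaSignal, spike_times: np.ndarray) -> Optional[SpikePhaseStats]:
    """Mean resultant vector of spike theta phases; None below one spike."""
    st = np.asarray(spike_times, dtype=int)
    st = st[(st >= 0) & (st < len(theta.phase))]
    if st.size < 1:
        return None
    phasors = np.exp(1j * theta.phase[st])
    mean = phasors.mean()
    return SpikePhaseStats(
        preferred_phase=float(np.angle(mean)),
        vector_length=float(np.abs(mean)),
        n_spikes=int(st.size),
    )
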