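"""Companion extracellular procedures.

LFP conditioning (anti-aliased downsample to 2.5 kHz, zero-phase bandstops
at 60/120/180 Hz), sharp-wave-ripple detection on the binned RMS of the
120-200 Hz band, two-class unit clustering (PCA + k-means on z-scored
waveform/rate features) and per-unit odor-response quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "UnitFeatures",
    "RippleEvent",
    "OdorResponse",
    "preprocess_lfp",
    "detect_ripples",
    "classify_units",
    "odor_response",
]

LFP_FS = 2500.0
RIPPLE_BAND = (120.0, 200.0)
RIPPLE_ENTER_SD = 10.0
RIPPLE_EXIT_SD = 2.0
RIPPLE_MIN_MS = 40.0
RIPPLE_MERGE_MS = 50.0
RMS_BIN_MS = 10.0
RATE_FLOOR_HZ = 0.5


@dataclass
class UnitFeatures:
    peak_trough_ms: float
    peak_trough_ratio: float
    mean_rate_hz: float
    unit_class: Optional[str] = None  # broad | narrow


@dataclass
class RippleEvent:
    start_ms: float
    end_ms: float
    peak_amplitude_sd: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class OdorResponse:
    response: float  # mean baseline-normalized smoothed rate over odor1
    sign_class: str  # odor-excited | odor-inhibited
    latency_class: str  # early (<200 ms) | late (>=200 ms)
    peak_latency_ms: float


def preprocess_lfp(raw: np.ndarray, fs: float) -> np.ndarray:
    """Downsample to 2.5 kHz (anti-aliased) and notch out 60 Hz line noise
    plus its 120/180 Hz harmonics with zero-phase 2nd-order bandstops."""
    if fs < LFP_FS:
        raise ValueError(f"sampling rate must be >= {LFP_FS} Hz, got {fs}")
    x = np.asarray(raw, dtype=float)
    if fs > LFP_FS:
        up, down = 1, int(round(fs / LFP_FS))
        if abs(fs / down - LFP_FS) > 1e-6:
            # non-integer ratio: polyphase resample
            from fractions import Fraction

            frac = Fraction(LFP_FS / fs).limit_denominator(1000)
            up, down = frac.numerator, frac.denominator
        x = signal.resample_poly(x, up, down)
    for f0 in (60.0, 120.0, 180.0):
        b, a = signal.butter(2, [f0 - 2.0, f0 + 2.0], btype="bandstop", fs=LFP_FS)
        x = signal.filtfilt(b, a, x)
    return x


def detect_ripples(
    lfp: np.ndarray,
    fs: float = LFP_FS,
    rms_bin_ms: float = RMS_BIN_MS,
) -> list[RippleEvent]:
    """Ripples from the 120-200 Hz band of a conditioned LFP.

    Events start when the binned RMS amplitude exceeds 10 s.d. (z-scored),
    with boundaries extended outward to the 2-s.d. crossings; events closer
    than 50 ms are concatenated and events shorter than 40 ms discarded.
    """
    x = np.asarray(lfp, dtype=float)
    if x.std() == 0:
        raise ValueError("zero-variance LFP")
    b, a = signal.butter(3, list(RIPPLE_BAND), btype="bandpass", fs=fs)
    band = signal.filtfilt(b, a, x)
    bin_n = max(int(round(rms_bin_ms * fs / 1000.0)), 1)
    nb = len(band) // bin_n
    rms = np.sqrt(np.mean(band[: nb * bin_n].reshape(nb, bin_n) ** 2, axis=1))
    # robust background stats so sparse high-amplitude events do not
    # inflate the s.d. they are thresholded against
    mu = float(np.median(rms))
    sd = 1.4826 * float(np.median(np.abs(rms - mu)))
    if sd == 0:
        raise ValueError("zero-variance RMS amplitude")
    z = (rms - mu) / sd

    events: list[tuple[int, int, float]] = []  # bin indices
    above = np.nonzero(z > RIPPLE_ENTER_SD)[0]
    visited_until = -1
    for i in above:
        if i <= visited_until:
            continue
        lo = i
        while lo > 0 and z[lo - 1] > RIPPLE_EXIT_SD:
            lo -= 1
        hi = i
        while hi < nb - 1 and z[hi + 1] > RIPPLE_EXIT_SD:
            hi += 1
        events.append((lo, hi + 1, float(z[lo: hi + 1].max())))
        visited_until = hi
    bin_ms = bin_n / fs * 1000.0

    merged: list[list[float]] = []
    for lo, hi, peak in events:
        s, e = lo * bin_ms, hi * bin_ms
        if merged and s - merged[-1][1] < RIPPLE_MERGE_MS:
            merged[-1][1] = e
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([s, e, peak])
    return [
        RippleEvent(start_ms=s, end_ms=e, peak_amplitude_sd=p)
        for s, e, p in merged
        if e - s >= RIPPLE_MIN_MS
    ]


def classify_units(features: Sequence[UnitFeatures], seed: int = 0) -> list[str]:
    """Cluster units into broad (pyramidal) and narrow (interneuron) classes.

    The three features (peak-trough distance, peak-trough amplitude ratio,
    mean rate) are z-scored, projected on their principal components, and
    split by k-means (k = 2, squared Euclidean distance, 100 restarts).
    The cluster with shorter peak-trough distance and higher rate is
    labeled narrow.  Units below the 0.5-Hz rate floor must be removed
    upstream.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    feats = np.array(
        [[u.peak_trough_ms, u.peak_trough_ratio, u.mean_rate_hz] for u in features]
    )
    if len(feats) < 2:
        raise ValueError("need >= 2 units")
    if np.any(feats[:, 2] < RATE_FLOOR_HZ):
        raise ValueError(f"units below the {RATE_FLOOR_HZ}-Hz rate floor present")
    sd = feats.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate clustering: a feature has zero variance")
    z = (feats - feats.mean(axis=0)) / sd
    scores = PCA(n_components=3).fit_transform(z)
    km = KMeans(n_clusters=2, n_init=100, random_state=seed).fit(scores)
    labels = km.labels_
    # narrow cluster: shorter peak-trough distance and higher rate
    pt0 = feats[labels == 0, 0].mean()
    pt1 = feats[labels == 1, 0].mean()
    narrow_label = 0 if pt0 < pt1 else 1
    return ["narrow" if l == narrow_label else "broad" for l in labels]


def odor_response(
    spike_trains: Sequence[np.ndarray],
    odor_onset_ms: float = 1000.0,
    odor_offset_ms: float = 2000.0,
    trial_len_ms: int = 11000,
    bin_ms: float = 10.0,
    gaussian_window_ms: float = 50.0,
) -> Optional[OdorResponse]:
    """Baseline-normalized odor response of one unit over its trials.

    10-ms binned rates are smoothed with a 50-ms Gaussian-weighted average,
    divided by the mean rate over the 1 s before the first odor, and
    averaged across the odor window.  Sign class is excited iff the
    response is strictly above the no-change level (1.0); latency class
    splits at a 200-ms peak latency.  Zero-baseline units are excluded.
    """
    edges = np.arange(0, trial_len_ms + bin_ms, bin_ms)
    n_bins = len(edges) - 1
    mean_counts = np.zeros(n_bins)
    for st in spike_trains:
        c, _ = np.histogram(st, bins=edges)
        mean_counts += c
    mean_rate = mean_counts / len(spike_trains) / (bin_ms / 1000.0)
    m = max(int(round(gaussian_window_ms / bin_ms)), 3)
    kern = signal.windows.gaussian(m, std=m / 5.0)
    kern /= kern.sum()
    # edge-normalized convolution: no zero-pad shrinkage at trace ends
    smoothed = np.convolve(mean_rate, kern, mode="same") / np.convolve(
        np.ones_like(mean_rate), kern, mode="same"
    )
    centers = edges[:-1] + bin_ms / 2.0
    base_sel = (centers >= odor_onset_ms - 1000.0) & (centers < odor_onset_ms)
    baseline = smoothed[base_sel].mean()
    if baseline == 0:
        warnings.warn("zero baseline rate; unit excluded from odor response")
        return None
    norm = smoothed / baseline
    odor_sel = (centers >= odor_onset_ms) & (centers < odor_offset_ms)
    response = float(norm[odor_sel].mean())
    odor_norm = norm[odor_sel]
    peak_latency = float(centers[odor_sel][np.argmax(odor_norm)] - odor_onset_ms)
    return OdorResponse(
        response=response,
        # excited iff strictly above no-change (small tolerance so exact
        # stationarity is not decided by rounding noise)
        sign_class="odor-excited" if response > 1.0 + 1e-9 else "odor-inhibited",
        latency_class="early" if peak_latency < 200.0 else "late",
        peak_latency_ms=peak_latency,
    )
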