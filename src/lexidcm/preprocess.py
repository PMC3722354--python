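"""Sensor-space preprocessing: filtering, epoching, robust averaging, global
field power and pointwise group comparisons.

The processing chain mirrors a standard evoked-response pipeline at a 480 Hz
recording rate: 1 Hz high-pass, epoching from -100 to 1000 ms peristimulus
with prestimulus baseline correction, 30 Hz low-pass, trial averaging with
iteratively reweighted (bisquare) robust weights, a repeat of the 30 Hz
low-pass to remove any high-frequency structure introduced by the weighting,
and global field power computed as the sum over sensors of squared amplitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .containers import EpochSet, Evoked, GFPSeries

__all__ = [
    "bandpass",
    "highpass",
    "lowpass",
    "epoch_and_baseline",
    "robust_average",
    "global_field_power",
    "find_peak",
    "pointwise_ttest",
    "SignificantWindow",
]

log = logging.getLogger(__name__)

FILTER_ORDER = 5  # Butterworth, applied forward-backward (zero phase)


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if data.shape[-1] <= padlen * 3:
        raise ValueError(
            f"window of {data.shape[-1]} samples too short for the filter order"
        )
    return signal.sosfiltfilt(sos, data, axis=-1)


def highpass(data: np.ndarray, sfreq: float, cutoff_hz: float = 1.0) -> np.ndarray:
    sos = signal.butter(FILTER_ORDER, cutoff_hz, btype="highpass", fs=sfreq, output="sos")
    return _sos_filtfilt(np.asarray(data, float), sos)


def lowpass(data: np.ndarray, sfreq: float, cutoff_hz: float = 30.0) -> np.ndarray:
    sos = signal.butter(FILTER_ORDER, cutoff_hz, btype="lowpass", fs=sfreq, output="sos")
    return _sos_filtfilt(np.asarray(data, float), sos)


def bandpass(
    data: np.ndarray, sfreq: float, high_pass_hz: float = 1.0, low_pass_hz: float = 30.0
) -> np.ndarray:
    """Zero-phase band-limiting along the last (time) axis."""
    if sfreq <= 2.0 * low_pass_hz:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    return lowpass(highpass(data, sfreq, high_pass_hz), sfreq, low_pass_hz)


def epoch_and_baseline(
    continuous: np.ndarray,
    event_samples: np.ndarray,
    sfreq: float = 480.0,
    window_ms: tuple[float, float] = (-100.0, 1000.0),
    conditions: list[str] | None = None,
) -> EpochSet:
    """Cut trials around events and subtract the prestimulus mean.

    ``continuous`` is sensors x samples.  An event at sample s yields the
    inclusive sample range s+round(w0*sfreq) .. s+round(w1*sfreq).  Events too
    close to the record edges are dropped with a log entry.  After baseline
    correction the prestimulus mean of every trial and sensor is exactly 0.
    """
    continuous = np.atleast_2d(np.asarray(continuous, float))
    dt = 1.0 / sfreq
    i0 = int(round(window_ms[0] / 1000.0 * sfreq))
    i1 = int(round(window_ms[1] / 1000.0 * sfreq))
    times_ms = np.arange(i0, i1 + 1) * dt * 1000.0
    n = continuous.shape[1]
    trials, kept = [], []
    for k, s in enumerate(np.asarray(event_samples, int)):
        lo, hi = s + i0, s + i1
        if lo < 0 or hi >= n:
            log.warning("dropping event at sample %d: window [%d, %d] outside record", s, lo, hi)
            continue
        trials.append(continuous[:, lo : hi + 1])
        kept.append(k)
    if not trials:
        raise ValueError("no events left room for the full epoch window")
    data = np.stack(trials)
    pres = times_ms < 0
    if not pres.any():
        raise ValueError("epoch window contains no prestimulus samples")
    data = data - data[:, :, pres].mean(axis=2, keepdims=True)
    if conditions is None:
        labels = ["" for _ in kept]
    else:
        labels = [conditions[k] for k in kept]
    return EpochSet(data, times_ms, labels, dt=dt, provenance="epoched+baseline")


BISQUARE_C = 4.685
ROBUST_MAX_ITER = 8
ROBUST_TOL = 1e-6
ROBUST_SMOOTH_S = 0.2  # weight-smoothing window along time, seconds


def robust_average(
    epochs: EpochSet,
    condition: str | None = None,
    relowpass_hz: float | None = 30.0,
) -> Evoked:
    """Iteratively reweighted trial average with bisquare weights.

    Weights are computed per sensor and time sample across trials, with the
    scale set by the median absolute deviation (tuning constant 4.685 * MAD,
    MAD rescaled to Gaussian SD), then smoothed along time (0.2 s window) so
    clean data are not chased sample by sample.  On clean Gaussian data the
    result is close to the arithmetic mean; artifact trials are
    down-weighted.  The returned Evoked carries trials x time weights
    averaged over sensors.  After averaging, the 30 Hz low-pass is repeated
    (disable by passing ``relowpass_hz=None``).
    """
    sub = epochs.select(condition) if condition is not None else epochs
    if sub.n_trials < 2:
        raise ValueError("robust averaging needs at least 2 trials")
    x = sub.data  # (trials, sensors, time)
    w = np.ones_like(x)
    mean = x.mean(axis=0)
    converged = False
    for _ in range(ROBUST_MAX_ITER):
        resid = x - mean[None]
        mad = np.median(np.abs(resid - np.median(resid, axis=0)), axis=0)
        scale = 1.4826 * mad
        # samples with no spread beyond float noise keep full weight
        degenerate = scale <= 1e-10 * np.sqrt(np.mean(x ** 2))
        scale = np.where(degenerate, 1.0, scale)
        u = resid / (BISQUARE_C * scale[None])
        w_new = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        w_new[:, degenerate] = 1.0
        win = min(x.shape[2], max(1, int(round(ROBUST_SMOOTH_S / sub.dt))))
        if win > 1:
            from scipy.ndimage import uniform_filter1d

            w_new = uniform_filter1d(w_new, size=win, axis=2, mode="nearest")
        denom = w_new.sum(axis=0)
        denom[denom <= 0] = 1.0
        mean = (w_new * x).sum(axis=0) / denom
        if np.max(np.abs(w_new - w)) < ROBUST_TOL:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        warnings.warn("robust averaging did not converge; returning last iterate")
    if relowpass_hz is not None:
        mean = lowpass(mean, 1.0 / sub.dt, relowpass_hz)
    label = condition if condition is not None else (sub.conditions[0] if sub.conditions else "")
    return Evoked(mean, sub.times_ms, label, weights=w.mean(axis=1), dt=sub.dt)


def global_field_power(evoked: Evoked) -> GFPSeries:
    """GFP(t) = sum over sensors of data(s, t)^2."""
    if evoked.data.shape[0] < 1:
        raise ValueError("need at least one sensor")
    return GFPSeries(np.sum(evoked.data ** 2, axis=0), evoked.times_ms)


def find_peak(gfp: GFPSeries, search_window_ms: tuple[float, float] = (140.0, 220.0)) -> float:
    """Latency (ms) of the GFP maximum inside the search window; ties break
    to the earliest sample."""
    m = (gfp.times_ms >= search_window_ms[0]) & (gfp.times_ms <= search_window_ms[1])
    if not m.any():
        raise ValueError("search window contains no samples")
    vals = gfp.values[m]
    times = gfp.times_ms[m]
    return float(times[int(np.argmax(vals))])


@dataclass
class SignificantWindow:
    start_ms: float
    end_ms: float
    peak_ms: float
    peak_t: float


def pointwise_ttest(
    gfp_a: np.ndarray,
    gfp_b: np.ndarray,
    times_ms: np.ndarray,
    paired: bool = True,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list[SignificantWindow]]:
    """Per-sample t-test between two groups of GFP series.

    ``gfp_a``/``gfp_b`` are subjects x time.  Returns (t, p, windows), where
    windows are maximal runs of contiguous samples with p < alpha
    (uncorrected for multiple comparisons).
    """
    a = np.atleast_2d(np.asarray(gfp_a, float))
    b = np.atleast_2d(np.asarray(gfp_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired test requires equal subject counts")
    if paired:
        t, p = stats.ttest_rel(a, b, axis=0)
    else:
        t, p = stats.ttest_ind(a, b, axis=0)
    sig = p < alpha
    windows: list[SignificantWindow] = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            k = i + int(np.argmax(np.abs(t[seg])))
            windows.append(
                SignificantWindow(
                    float(times_ms[i]), float(times_ms[j]), float(times_ms[k]), float(t[k])
                )
            )
            i = j + 1
        else:
            i += 1
    return t, p, windows
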