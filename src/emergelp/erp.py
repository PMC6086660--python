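"""Event-related potential construction and timecourse analyses.

Stimulus-locked ERPs average the trials on which a detected event followed the
stimulus within 2 s; peak-locked waveforms average raw segments centered on
detected event peaks (removing the stimulus-latency jitter that attenuates
stimulus-locked amplitudes). Morphology is summarized by rise/fall times at a
200 µV threshold. Timecourse analyses track the normalized ERP amplitude in
60 s windows sliding by 15 s around the behavioral markers, and in labeled
3-minute condition epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Recording, Trials

logger = logging.getLogger(__name__)


@dataclass
class ERPResult:
    """Time-locked average waveform with dispersion and trial counts."""

    timebase: np.ndarray  # s relative to the lock point
    waveform: np.ndarray  # µV
    dispersion: np.ndarray  # s.e.m. (mean) or stacked quartiles (median)
    n_trials: int
    lock: str  # "stimulus" | "peak"

    def peak(self, window: tuple[float, float] | None = None):
        """(latency_s, signed_amplitude) of the absolute extremum."""
        m = np.ones_like(self.timebase, dtype=bool)
        if window is not None:
            m = (self.timebase >= window[0]) & (self.timebase <= window[1])
        i = np.flatnonzero(m)[np.argmax(np.abs(self.waveform[m]))]
        return float(self.timebase[i]), float(self.waveform[i])


def event_trial_mask(trials: Trials, events: pd.DataFrame,
                     window_s: float = 2.0) -> np.ndarray:
    """(n_trials, n_channels) mask: a detected event on that channel followed
    the trial's stimulus within ``window_s`` seconds."""
    mask = np.zeros((trials.n_trials, len(trials.channel_names)), dtype=bool)
    for ch, name in enumerate(trials.channel_names):
        peaks = events.loc[events["channel"] == name, "peak_time_s"].to_numpy()
        if not peaks.size:
            continue
        for k, onset in enumerate(trials.onsets):
            d = peaks - onset
            if np.any((d > 0.0) & (d <= window_s)):
                mask[k, ch] = True
    return mask


def stimulus_locked_erp(trials: Trials, event_mask: np.ndarray | None = None,
                        min_trials: int = 5, sign_flip: bool = True):
    """Per-channel mean over (event) trials; channels below ``min_trials`` drop.

    Returns ``{channel_name: ERPResult}``. With ``sign_flip`` each channel's
    waveform is oriented so the dominant deflection is negative, matching the
    display convention for K-complex-like events.
    """
    out: dict[str, ERPResult] = {}
    for ch, name in enumerate(trials.channel_names):
        keep = ~trials.rejected[:, ch]
        if event_mask is not None:
            keep &= event_mask[:, ch]
        n = int(keep.sum())
        if n < min_trials:
            continue
        data = trials.data[keep, ch, :]
        mean = data.mean(axis=0)
        sem = data.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        if sign_flip and mean[np.argmax(np.abs(mean))] > 0:
            mean = -mean
        out[name] = ERPResult(trials.times.copy(), mean, sem, n, "stimulus")
    return out


def pool_erps(erps: list[ERPResult]) -> ERPResult:
    """Cohort median waveform with quartile dispersion across channels."""
    if not erps:
        raise ValueError("no waveforms to pool")
    stack = np.stack([e.waveform for e in erps])
    med = np.median(stack, axis=0)
    quarts = np.percentile(stack, [25, 75], axis=0)
    return ERPResult(erps[0].timebase.copy(), med, quarts, len(erps), erps[0].lock)


def peak_locked_waveform(signal: np.ndarray, fs: float, event_times,
                         window: tuple[float, float] = (-2.5, 2.5)) -> ERPResult:
    """Mean waveform of a channel centered on detected event peaks.

    Events whose window exceeds the recording bounds are skipped (logged).
    """
    event_times = np.asarray(event_times, dtype=float)
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    times = np.arange(i0, i1) / fs
    segs = []
    for t in event_times:
        c = int(round(t * fs))
        if c + i0 < 0 or c + i1 > signal.size:
            logger.info("event at %.2f s too close to edge; skipped", t)
            continue
        segs.append(signal[c + i0:c + i1])
    if not segs:
        raise ValueError("no events fit within the recording")
    data = np.stack(segs)
    mean = data.mean(axis=0)
    sem = (data.std(axis=0, ddof=1) / np.sqrt(len(segs))
           if len(segs) > 1 else np.zeros_like(mean))
    return ERPResult(times, mean, sem, len(segs), "peak")


def rise_fall_times(waveform: ERPResult | np.ndarray, threshold: float = 200.0,
                    timebase: np.ndarray | None = None):
    """Rise and fall times (ms) at ``threshold`` µV around the waveform peak.

    Works on the absolute waveform so sign-flipped (negative) averages are
    supported. Rise is the time from the last upward threshold crossing to
    the peak; fall from the peak to the next downward crossing, both with
    linear sub-sample interpolation. A peak below threshold is undefined and
    returns ``(nan, nan)`` with a warning.
    """
    if isinstance(waveform, ERPResult):
        t, w = waveform.timebase, waveform.waveform
    else:
        w = np.asarray(waveform, dtype=float)
        t = np.arange(w.size) if timebase is None else np.asarray(timebase)
    p = np.abs(w)
    i_pk = int(np.argmax(p))
    if p[i_pk] <= threshold:
        logger.warning("waveform peak %.1f µV below %.0f µV threshold", p[i_pk], threshold)
        return float("nan"), float("nan")

    def cross(i, step):
        j = i
        while 0 < j < p.size - 1 and p[j + step] >= threshold:
            j += step
        j2 = j + step
        if not (0 <= j2 < p.size) or p[j2] >= threshold:
            return t[j]  # never crosses inside the window
        frac = (p[j] - threshold) / (p[j] - p[j2])
        return t[j] + frac * (t[j2] - t[j])

    rise = (t[i_pk] - cross(i_pk, -1)) * 1000.0
    fall = (cross(i_pk, +1) - t[i_pk]) * 1000.0
    return float(rise), float(fall)


@dataclass
class TimecourseResult:
    """Sliding-window ERP amplitude timecourse around behavioral markers."""

    window_centers: np.ndarray  # s (absolute recording time)
    z: np.ndarray  # peak ERP z per window (nan where masked)
    n_stimuli: np.ndarray
    valid: np.ndarray  # windows with >= min_stimuli trials

    def aligned_to(self, marker_time: float) -> np.ndarray:
        return self.window_centers - marker_time


def sliding_zscore_timecourse(trials: Trials, channel: int, duration: float,
                              window_s: float = 60.0, step_s: float = 15.0,
                              baseline_s: float = 1.5, min_stimuli: int = 8,
                              post_window: tuple[float, float] = (0.0, 2.0)) -> TimecourseResult:
    """Normalized ERP amplitude in 60 s windows sliding every 15 s.

    Within each window, the ERP is the mean of all (artifact-free) trials on
    the chosen channel; its post-stimulus peak is normalized by the standard
    deviation of the pre-stimulus ``baseline_s`` samples pooled over the
    window's trials. Windows with fewer than ``min_stimuli`` trials carry no
    value.
    """
    centers = np.arange(window_s / 2.0, duration - window_s / 2.0 + 1e-9, step_s)
    if centers.size == 0:
        logger.warning("recording shorter than one timecourse window")
        return TimecourseResult(centers, np.array([]), np.array([], dtype=int),
                                np.array([], dtype=bool))
    pre = (trials.times >= -baseline_s) & (trials.times < 0.0)
    post = (trials.times >= post_window[0]) & (trials.times <= post_window[1])
    z = np.full(centers.size, np.nan)
    n_stim = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        sel = (np.abs(trials.onsets - c) <= window_s / 2.0) & ~trials.rejected[:, channel]
        n_stim[i] = int(sel.sum())
        if n_stim[i] < min_stimuli:
            continue
        data = trials.data[sel, channel, :]
        erp = data.mean(axis=0)
        sd = data[:, pre].std()
        if sd > 0:
            z[i] = np.max(np.abs(erp[post])) / sd
    valid = n_stim >= min_stimuli
    return TimecourseResult(centers, z, n_stim, valid)


def epoch_erp_amplitude(trials: Trials, channel: int,
                        epochs: dict[str, tuple[float, float]],
                        post_window: tuple[float, float] = (0.5, 1.5)) -> pd.Series:
    """|mean ERP| averaged over ``post_window`` for each labeled epoch.

    Epochs (e.g. baseline / sedation / post-LOC / propofol-off pre-ROC /
    post-ROC, 3 minutes each) with no usable stimuli yield NaN.
    """
    post = (trials.times >= post_window[0]) & (trials.times <= post_window[1])
    out = {}
    for label, (a, b) in epochs.items():
        sel = (trials.onsets >= a) & (trials.onsets < b) & ~trials.rejected[:, channel]
        if not sel.any():
            out[label] = np.nan
            continue
        erp = trials.data[sel, channel, :].mean(axis=0)
        out[label] = float(np.abs(erp[post].mean()))
    return pd.Series(out)
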