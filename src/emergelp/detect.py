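"""Automated LP / K-complex detection.

The intracranial detector filters each channel to 0.2–4 Hz and keeps peaks of
either sign with amplitude >= 400 µV that stay beyond 40 µV (same sign as the
peak) for >= 400 ms; peaks above 1200 µV are discarded as artifact, events
within 500 ms of a kept event are discarded, and all events on a channel must
share the majority polarity. The scalp variant normalizes each trial to its
2 s pre-stimulus baseline and detects trials whose post-stimulus peak exceeds
a z threshold (7 s.d. by default, 5 for the relaxed setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import Recording, Trials

logger = logging.getLogger(__name__)


@dataclass
class DetectorParams:
    band: tuple[float, float] = (0.2, 4.0)
    min_peak: float = 400.0  # µV on the band-filtered trace
    duration_threshold: float = 40.0  # µV
    min_duration: float = 0.4  # s beyond duration_threshold
    artifact_peak: float = 1200.0  # µV; larger peaks discarded
    refractory: float = 0.5  # s; later event discarded
    min_events_per_channel: int = 5

    def __post_init__(self):
        if not self.min_peak > self.duration_threshold:
            raise ValueError("min_peak must exceed duration_threshold")
        if not self.artifact_peak > self.min_peak:
            raise ValueError("artifact_peak must exceed min_peak")


@dataclass
class DetectedEvent:
    channel: str
    peak_time: float  # s
    peak_amplitude: float  # signed µV, on the band-filtered trace
    supra_duration: float  # s beyond the 40 µV threshold
    polarity: int  # ±1
    evoked: bool | None = None
    stimulus_index: int | None = None


def band_filter(signal: np.ndarray, fs: float,
                band: tuple[float, float] = (0.2, 4.0)) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass used by the detector."""
    sos = sps.butter(4, np.asarray(band) / (fs / 2.0), btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def detect_lp_channel(signal: np.ndarray, fs: float,
                      params: DetectorParams | None = None,
                      window: tuple[float, float] | None = None,
                      channel: str = "ch") -> list[DetectedEvent]:
    """Detect candidate LP events on one channel.

    Rules are applied in a fixed order: band filter; enumerate positive and
    negative peaks with |amplitude| >= ``min_peak``; require the contiguous
    same-sign excursion beyond ``duration_threshold`` containing the peak to
    last >= ``min_duration``; drop peaks with |amplitude| > ``artifact_peak``;
    then walk events in time order dropping any within ``refractory`` of the
    last kept event. Polarity consistency is enforced separately by
    :func:`enforce_polarity`.
    """
    params = params or DetectorParams()
    x = band_filter(np.asarray(signal, dtype=float), fs, params.band)
    if window is None:
        window = (0.0, x.size / fs)
    if window[1] - window[0] < params.min_duration:
        return []
    pos, _ = sps.find_peaks(x, height=params.min_peak)
    neg, _ = sps.find_peaks(-x, height=params.min_peak)
    idx = np.sort(np.concatenate([pos, neg]))
    lo, hi = int(np.ceil(window[0] * fs)), int(np.floor(window[1] * fs))
    idx = idx[(idx >= lo) & (idx < min(hi, x.size))]

    supra_pos = x >= params.duration_threshold
    supra_neg = x <= -params.duration_threshold
    events = []
    for i in idx:
        amp = x[i]
        sign = 1 if amp > 0 else -1
        supra = supra_pos if sign > 0 else supra_neg
        j0 = i
        while j0 > 0 and supra[j0 - 1]:
            j0 -= 1
        j1 = i
        while j1 < x.size - 1 and supra[j1 + 1]:
            j1 += 1
        duration = (j1 - j0 + 1) / fs
        if duration < params.min_duration:
            continue
        if abs(amp) > params.artifact_peak:
            continue
        events.append(DetectedEvent(channel=channel, peak_time=i / fs,
                                    peak_amplitude=float(amp), supra_duration=duration,
                                    polarity=sign))
    kept = []
    last = -np.inf
    for ev in events:  # already in time order
        if ev.peak_time - last < params.refractory:
            continue
        kept.append(ev)
        last = ev.peak_time
    return kept


def enforce_polarity(events: list[DetectedEvent]):
    """Keep only majority-polarity events of one channel.

    Returns ``(events, dominant_polarity)``; the tie-break is negative (the
    conventional surface polarity of K-complexes) and is logged when invoked.
    Empty input yields ``([], None)``.
    """
    if not events:
        return [], None
    n_pos = sum(1 for e in events if e.polarity > 0)
    n_neg = len(events) - n_pos
    if n_pos == n_neg:
        logger.info("polarity tie on channel %s; keeping negative", events[0].channel)
    dominant = 1 if n_pos > n_neg else -1
    return [e for e in events if e.polarity == dominant], dominant


def classify_evoked(events: list[DetectedEvent], stimuli: pd.DataFrame,
                    window_s: float = 2.0) -> list[DetectedEvent]:
    """Flag events whose peak falls within ``window_s`` after a stimulus.

    The nearest qualifying stimulus (largest onset not after the peak) is
    recorded in ``stimulus_index``; all other events are spontaneous.
    """
    onsets = np.sort(stimuli["onset_s"].to_numpy()) if len(stimuli) else np.array([])
    for ev in events:
        ev.evoked = False
        ev.stimulus_index = None
        if onsets.size:
            k = int(np.searchsorted(onsets, ev.peak_time, side="left")) - 1
            if k >= 0 and 0.0 < ev.peak_time - onsets[k] <= window_s:
                ev.evoked = True
                ev.stimulus_index = k
    return events


def detect_recording(rec: Recording, params: DetectorParams | None = None) -> pd.DataFrame:
    """Run the detector over all good channels of a recording.

    Applies per-channel detection within the recording's analysis window,
    polarity enforcement, and evoked/spontaneous classification. Returns a
    tidy event table.
    """
    params = params or DetectorParams()
    rows = []
    for ch, info in enumerate(rec.channels):
        if info.is_bad:
            continue
        events = detect_lp_channel(rec.samples[ch], rec.fs, params,
                                   window=rec.analysis_window, channel=info.name)
        events, _ = enforce_polarity(events)
        events = classify_evoked(events, rec.stimuli)
        for e in events:
            rows.append({"channel": e.channel, "peak_time_s": e.peak_time,
                         "amplitude_uV": e.peak_amplitude,
                         "duration_s": e.supra_duration, "polarity": e.polarity,
                         "evoked": e.evoked,
                         "stimulus_index": -1 if e.stimulus_index is None else e.stimulus_index})
    return pd.DataFrame(rows, columns=["channel", "peak_time_s", "amplitude_uV",
                                       "duration_s", "polarity", "evoked",
                                       "stimulus_index"])


def qualifying_channels(events: pd.DataFrame, params: DetectorParams | None = None):
    """Channels with >= ``min_events_per_channel`` events, plus the busiest one.

    Returns ``(channel_names, max_event_channel)``; the per-subject
    maximum-event channel anchors the peak-locked waveform and spectral
    analyses.
    """
    params = params or DetectorParams()
    if not len(events):
        return [], None
    counts = events.groupby("channel").size().sort_values(ascending=False)
    qual = sorted(counts[counts >= params.min_events_per_channel].index.tolist())
    return qual, counts.index[0]


def detect_lp_scalp(trials: Trials, channel: int = 0, z_threshold: float = 7.0,
                    baseline_s: float = 2.0, post_s: float = 1.0) -> pd.DataFrame:
    """Scalp-EEG LP detection on baseline-normalized trials.

    Each trial is normalized by the mean and s.d. of its 2 s pre-stimulus
    baseline; the statistic is the maximum |z| during the 1 s following
    stimulus onset, and a trial is a detection when it exceeds
    ``z_threshold`` (7 s.d.; 5 for the relaxed setting). Trials with zero
    baseline variance are skipped with a warning.
    """
    t = trials.times
    base = (t >= -baseline_s) & (t < 0.0)
    post = (t > 0.0) & (t <= post_s)
    if not base.any():
        raise ValueError("trials lack the pre-stimulus baseline")
    rows = []
    for k in range(trials.n_trials):
        x = trials.data[k, channel]
        mu, sd = x[base].mean(), x[base].std()
        if sd == 0.0:
            logger.warning("trial %d has zero baseline variance; skipped", k)
            continue
        z = np.max(np.abs((x[post] - mu) / sd))
        rows.append({"trial": k, "onset_s": trials.onsets[k], "max_z": float(z),
                     "detected": bool(z > z_threshold)})
    return pd.DataFrame(rows, columns=["trial", "onset_s", "max_z", "detected"])
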