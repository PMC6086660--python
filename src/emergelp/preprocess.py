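"""Re-referencing, filtering, segmentation and artifact screening.

This module holds the universal carriers of the pipeline: :class:`Recording`
(multichannel voltage time series in µV with stimulus/behavioral annotations)
and :class:`Trials` (stimulus-locked epochs with an artifact-rejection mask),
plus the standard conditioning chain applied to intracranial recordings
before event detection: montage re-referencing, detrending, band limiting
to ~0.16–200 Hz and downsampling to 500 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

TARGET_FS = 500.0


@dataclass
class ChannelInfo:
    """Metadata for one recording channel.

    ``neighbors`` (channel names) drive the Laplacian montage; ``probe`` and
    ``contact`` order contacts along a depth/strip probe for the bipolar
    montage. Channels flagged ``is_bad`` are excluded everywhere downstream.
    """

    name: str
    kind: str = "grid"  # grid | strip | depth | scalp
    region: str | None = None
    neighbors: list[str] = field(default_factory=list)
    is_bad: bool = False
    probe: str | None = None
    contact: int | None = None


@dataclass
class Recording:
    """Multichannel voltage recording (µV) with annotations.

    samples : (n_channels, n_samples) array, µV
    stimuli : DataFrame with columns ``onset_s`` and ``type``
    markers : mapping of behavioral marker name -> time (s); typical keys are
        ``infusion_stop``, ``loc``, ``first_movement``, ``first_response``
    analysis_window : (start_s, end_s) continuous segment used for automatic
        event detection (the synthetic default is the whole recording)
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    stimuli: pd.DataFrame = None
    markers: dict = field(default_factory=dict)
    analysis_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata does not match samples")
        if self.stimuli is None:
            self.stimuli = pd.DataFrame({"onset_s": [], "type": []})
        if self.analysis_window is None:
            self.analysis_window = (0.0, self.duration)
        a, b = self.analysis_window
        if not (0.0 <= a < b <= self.duration + 1e-9):
            raise ValueError("analysis_window outside recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def good_mask(self) -> np.ndarray:
        return np.array([not c.is_bad for c in self.channels])


@dataclass
class Trials:
    """Stimulus-locked epochs: ``data`` is (n_trials, n_channels, n_times)."""

    data: np.ndarray
    times: np.ndarray  # s relative to stimulus onset
    onsets: np.ndarray  # stimulus onset times (s)
    stim_index: np.ndarray  # row index into the recording's stimulus table
    rejected: np.ndarray  # (n_trials, n_channels) artifact mask
    fs: float
    channel_names: list[str]
    stim_types: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def rereference(rec: Recording, montage: str) -> Recording:
    """Re-reference a recording to a ``bipolar`` or ``laplacian`` montage.

    Bipolar subtracts the next contact of the same probe from each channel
    (the last contact of each probe is dropped). Laplacian subtracts the mean
    of the listed neighbor channels; channels with no usable neighbors are
    dropped with a warning rather than failing.
    """
    if montage not in ("bipolar", "laplacian"):
        raise ValueError(f"unknown montage {montage!r}")
    name_to_idx = {c.name: i for i, c in enumerate(rec.channels)}
    out_samples, out_channels = [], []
    if montage == "bipolar":
        probes: dict[str, list[ChannelInfo]] = {}
        for c in rec.channels:
            if c.is_bad:
                continue
            probes.setdefault(c.probe or c.name, []).append(c)
        for probe, chans in probes.items():
            chans = sorted(chans, key=lambda c: (c.contact if c.contact is not None else 0))
            if len(chans) < 2:
                logger.warning("bipolar: probe %s has a single contact; dropped", probe)
                continue
            for a, b in zip(chans[:-1], chans[1:]):
                out_samples.append(rec.samples[name_to_idx[a.name]] - rec.samples[name_to_idx[b.name]])
                out_channels.append(replace(a, name=f"{a.name}-{b.name}", neighbors=[]))
    else:
        for c in rec.channels:
            if c.is_bad:
                continue
            nb = [name_to_idx[n] for n in c.neighbors
                  if n in name_to_idx and not rec.channels[name_to_idx[n]].is_bad]
            if not nb:
                logger.warning("laplacian: channel %s has no neighbors; dropped", c.name)
                continue
            out_samples.append(rec.samples[name_to_idx[c.name]]
                               - rec.samples[nb].mean(axis=0))
            out_channels.append(replace(c))
    if not out_samples:
        raise ValueError("re-referencing dropped every channel")
    return Recording(np.array(out_samples), rec.fs, out_channels,
                     stimuli=rec.stimuli.copy(), markers=dict(rec.markers),
                     analysis_window=rec.analysis_window)


def _sos_filtfilt(samples, fs, cutoff, btype):
    sos = sps.butter(4, np.asarray(cutoff) / (fs / 2.0), btype=btype, output="sos")
    return sps.sosfiltfilt(sos, samples, axis=-1)


def filter_chain(rec: Recording, lowpass_hz: float = 200.0,
                 highpass_hz: float = 0.16, target_fs: float = TARGET_FS) -> Recording:
    """Detrend, lowpass < 200 Hz, downsample to 500 Hz, highpass > 0.16 Hz.

    Filters are zero-phase 4th-order Butterworth (forward-backward), so ERP
    latencies are not shifted. The input rate must be at least the target
    rate; no upsampling is performed and non-integer decimation is refused.
    """
    if rec.fs < target_fs:
        raise ValueError(f"input rate {rec.fs} Hz below target {target_fs} Hz")
    x = sps.detrend(rec.samples, axis=-1, type="linear")
    if lowpass_hz < rec.fs / 2.0:
        x = _sos_filtfilt(x, rec.fs, lowpass_hz, "lowpass")
    fs = rec.fs
    if fs != target_fs:
        q = fs / target_fs
        if abs(q - round(q)) > 1e-9:
            raise ValueError("non-integer decimation factor")
        x = sps.resample_poly(x, 1, int(round(q)), axis=-1)
        fs = target_fs
    x = _sos_filtfilt(x, fs, highpass_hz, "highpass")
    scale = fs / rec.fs
    stimuli = rec.stimuli.copy()
    a, b = rec.analysis_window
    return Recording(x, fs, [replace(c) for c in rec.channels], stimuli=stimuli,
                     markers=dict(rec.markers), analysis_window=(a, min(b, x.shape[1] / fs)))


def extract_trials(rec: Recording, window: tuple[float, float] = (-2.5, 2.5),
                   range_limit_uv: float = 1500.0) -> Trials:
    """Cut stimulus-locked trials and flag artifact trials.

    Trials whose peak-trough range exceeds ``range_limit_uv`` on a channel are
    flagged rejected on that channel. Stimuli too close to the recording edges
    are dropped (logged), keeping the per-trial matrices rectangular.
    """
    pre, post = window
    if post <= pre:
        raise ValueError("window end must exceed start")
    n = rec.samples.shape[1]
    i0, i1 = int(round(pre * rec.fs)), int(round(post * rec.fs))
    times = np.arange(i0, i1) / rec.fs
    rows, onsets, idx = [], [], []
    for k, onset in enumerate(rec.stimuli["onset_s"].to_numpy()):
        c = int(round(onset * rec.fs))
        if c + i0 < 0 or c + i1 > n:
            logger.info("trial %d at %.2f s too close to edge; dropped", k, onset)
            continue
        rows.append(rec.samples[:, c + i0:c + i1])
        onsets.append(onset)
        idx.append(k)
    if rows:
        data = np.stack(rows)
        rejected = np.ptp(data, axis=-1) > range_limit_uv
    else:
        data = np.empty((0, rec.n_channels, times.size))
        rejected = np.empty((0, rec.n_channels), dtype=bool)
    stim_types = rec.stimuli["type"].to_numpy()[idx] if len(idx) else np.array([])
    return Trials(data=data, times=times, onsets=np.asarray(onsets),
                  stim_index=np.asarray(idx, dtype=int), rejected=rejected,
                  fs=rec.fs, channel_names=rec.channel_names, stim_types=stim_types)
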