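"""Multitaper spectral estimation and cohort spectral statistics.

Tapers follow the convention NW = (K+1)/2 for K tapers, so the 3-taper
event-triggered spectrogram (200 ms window, 50 ms step) has NW = 2 and the
19-taper 30 s epoch spectrum has NW = 10; the spectral resolution used by the
contiguity rule of the hierarchical bootstrap is 2·NW/T. Power is expressed
as 10·log10 ratios (dB).

The module covers: event-triggered spectrograms normalized per frequency to a
[−2, −1] s pre-peak baseline; the gamma-band (40–100 Hz) DOWN-state
suppression statistic; 30 s epoch spectra with jackknife uncertainty;
hierarchical (subjects, then epochs) bootstrap comparison of cohort spectra;
10–40 Hz band-power comparison of matched electrodes across states; and the
40 Hz steady-state auditory response with its 22 Hz control frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal.windows import dpss

from .preprocess import Trials


@dataclass
class SpectralParams:
    spectrogram_tapers: int = 3
    spectrogram_window: float = 0.2  # s
    spectrogram_step: float = 0.05  # s
    epoch_tapers: int = 19
    epoch_length: float = 30.0  # s
    n_epochs: int = 6  # per 3-min window
    gamma_band: tuple[float, float] = (40.0, 100.0)
    comparison_band: tuple[float, float] = (10.0, 40.0)
    baseline: tuple[float, float] = (-2.0, -1.0)  # s pre-peak
    post_peak: float = 0.3  # s
    n_boot: int = 1000


@dataclass
class SpectralResult:
    """Spectrum or spectrogram in dB with its uncertainty band."""

    freqs: np.ndarray
    values: np.ndarray  # dB; (n_freq,) or (n_freq, n_times)
    times: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    n_segments: int = 0
    power: np.ndarray | None = None  # linear µV²/Hz, pre-dB (spectra only)


def _tapers(n: int, k: int) -> np.ndarray:
    nw = (k + 1) / 2.0
    return dpss(n, nw, Kmax=k)


def mt_psd(x: np.ndarray, fs: float, n_tapers: int,
           detrend: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of ``x`` (..., n_samples); one-sided, µV²/Hz.

    Each window is linearly detrended before tapering; without this, a large
    slow deflection inside a short window leaks broadband and can swamp the
    gamma-range power by orders of magnitude.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if detrend:
        t = np.arange(n) - (n - 1) / 2.0
        slope = (x * t).sum(axis=-1, keepdims=True) / (t * t).sum()
        x = x - x.mean(axis=-1, keepdims=True) - slope * t
    tapers = _tapers(n, n_tapers)  # (K, n), unit energy
    spec = np.fft.rfft(x[..., None, :] * tapers, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) / fs
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def spectral_resolution(n_tapers: int, window_s: float) -> float:
    """Half-bandwidth-based resolution 2·NW/T of the taper family, in Hz."""
    return 2.0 * ((n_tapers + 1) / 2.0) / window_s


def mt_spectrogram(signal: np.ndarray, fs: float, lock_times,
                   params: SpectralParams | None = None,
                   span: tuple[float, float] = (-2.5, 2.5),
                   normalize: bool = True) -> SpectralResult:
    """Event-triggered multitaper spectrogram, averaged over events.

    When ``normalize`` is set, each frequency row is expressed in dB relative
    to its mean power in the pre-peak baseline window, so baseline columns
    average exactly 0 dB. Events whose window exceeds the signal bounds are
    skipped.
    """
    params = params or SpectralParams()
    win_n = int(round(params.spectrogram_window * fs))
    step_n = int(round(params.spectrogram_step * fs))
    i0, i1 = int(round(span[0] * fs)), int(round(span[1] * fs))
    segs = []
    for t in np.asarray(lock_times, dtype=float):
        c = int(round(t * fs))
        if c + i0 < 0 or c + i1 > signal.size:
            continue
        segs.append(signal[c + i0:c + i1])
    if not segs:
        raise ValueError("no events fit within the signal")
    data = np.stack(segs)  # (n_ev, n_samp)
    starts = np.arange(0, data.shape[1] - win_n + 1, step_n)
    times = (starts + win_n / 2.0) / fs + span[0]
    windows = np.stack([data[:, s:s + win_n] for s in starts], axis=1)  # (ev, t, n)
    freqs, psd = mt_psd(windows, fs, params.spectrogram_tapers)  # (ev, t, f)
    mean_p = psd.mean(axis=0).T  # (f, t)
    if normalize:
        base = (times >= params.baseline[0]) & (times <= params.baseline[1])
        if not base.any():
            raise ValueError("baseline window outside spectrogram span")
        ref = mean_p[:, base].mean(axis=1, keepdims=True)
        values = 10.0 * np.log10(mean_p / ref)
    else:
        values = 10.0 * np.log10(mean_p)
    return SpectralResult(freqs=freqs, values=values, times=times,
                          n_segments=data.shape[0])


def event_gamma_change(spectrogram: SpectralResult,
                       params: SpectralParams | None = None) -> float:
    """Mean gamma (40–100 Hz) dB change in the post-peak window.

    Expects a peak-locked, baseline-normalized spectrogram; returns the mean
    normalized power over gamma frequencies and 0–300 ms post-peak — the
    DOWN-state suppression statistic for one subject.
    """
    params = params or SpectralParams()
    fm = ((spectrogram.freqs >= params.gamma_band[0])
          & (spectrogram.freqs <= params.gamma_band[1]))
    tm = (spectrogram.times >= 0.0) & (spectrogram.times <= params.post_peak)
    if not fm.any() or not tm.any():
        raise ValueError("gamma band or post-peak window empty")
    return float(spectrogram.values[np.ix_(fm, tm)].mean())


def cohort_gamma_test(changes, n_boot: int = 1000, seed=0):
    """Cohort summary of per-subject gamma changes.

    Returns ``(mean_db, signed_rank_p, (ci_lo, ci_hi))``; the CI resamples
    subjects with replacement. With fewer than two subjects the CI and test
    are unavailable (NaN).
    """
    changes = np.asarray(changes, dtype=float)
    mean = float(changes.mean())
    if changes.size < 2:
        return mean, float("nan"), (float("nan"), float("nan"))
    p = float(stats.wilcoxon(changes).pvalue)
    rng = np.random.default_rng(seed)
    boots = rng.choice(changes, size=(n_boot, changes.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return mean, p, (float(lo), float(hi))


def epoch_spectrum(signal: np.ndarray, fs: float,
                   params: SpectralParams | None = None,
                   artifact_sd: float = 500.0) -> SpectralResult:
    """Mean multitaper spectrum over consecutive 30 s epochs with jackknife bounds.

    Epochs whose standard deviation exceeds ``artifact_sd`` µV are excluded
    (motion-artifact screen). Raises if no complete epoch fits.
    """
    params = params or SpectralParams()
    n_ep = int(round(params.epoch_length * fs))
    n_avail = signal.size // n_ep
    if n_avail < 1:
        raise ValueError("signal shorter than one epoch")
    epochs = []
    for k in range(min(n_avail, params.n_epochs)):
        seg = signal[k * n_ep:(k + 1) * n_ep]
        if seg.std() > artifact_sd:
            continue
        epochs.append(seg - seg.mean())
    if not epochs:
        raise ValueError("all epochs rejected as artifact")
    freqs, psd = mt_psd(np.stack(epochs), fs, params.epoch_tapers)  # (n_ep, f)
    mean_p = psd.mean(axis=0)
    values = 10.0 * np.log10(mean_p)
    m = len(epochs)
    if m > 1:
        # leave-one-epoch-out jackknife on the dB spectrum
        loo = np.stack([10.0 * np.log10(np.delete(psd, k, axis=0).mean(axis=0))
                        for k in range(m)])
        se = np.sqrt((m - 1) / m * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
        tcrit = stats.t.ppf(0.975, m - 1)
        lower, upper = values - tcrit * se, values + tcrit * se
    else:
        lower = upper = values.copy()
    return SpectralResult(freqs=freqs, values=values, lower=lower, upper=upper,
                          n_segments=m, power=mean_p)


@dataclass
class BootstrapComparison:
    freqs: np.ndarray
    mean_diff_db: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray  # contiguity-filtered mask
    resolution_hz: float
    n_boot: int


def hierarchical_bootstrap_compare(spectra_a, spectra_b, freqs,
                                   n_boot: int = 1000, seed=0,
                                   resolution_hz: float | None = None,
                                   params: SpectralParams | None = None) -> BootstrapComparison:
    """Hierarchical bootstrap of a cohort spectral difference (a minus b).

    ``spectra_a``/``spectra_b`` are lists (one entry per subject) of
    (n_epochs, n_freq) linear-power epoch spectra. Each bootstrap draw
    resamples subjects with replacement, then epochs within each resampled
    subject, computes the two cohort mean spectra and their dB difference.
    Frequencies where the [2.5, 97.5] percentile band excludes zero are
    flagged, and only contiguous runs wider than the spectral resolution
    survive the contiguity rule.
    """
    params = params or SpectralParams()
    if n_boot < 100:
        raise ValueError("n_boot below 100 gives unstable percentiles")
    if len(spectra_a) < 2 or len(spectra_b) < 2:
        raise ValueError("need at least two subjects per cohort")
    if resolution_hz is None:
        resolution_hz = spectral_resolution(params.epoch_tapers, params.epoch_length)
    rng = np.random.default_rng(seed)
    a = [np.asarray(s, dtype=float) for s in spectra_a]
    b = [np.asarray(s, dtype=float) for s in spectra_b]

    def cohort_mean(spectra, rng):
        subj = rng.integers(len(spectra), size=len(spectra))
        means = []
        for i in subj:
            eps = spectra[i]
            ep = rng.integers(eps.shape[0], size=eps.shape[0])
            means.append(eps[ep].mean(axis=0))
        return np.mean(means, axis=0)

    diffs = np.empty((n_boot, len(freqs)))
    for k in range(n_boot):
        diffs[k] = 10.0 * np.log10(cohort_mean(a, rng) / cohort_mean(b, rng))
    lo, hi = np.percentile(diffs, [2.5, 97.5], axis=0)
    mean_diff = 10.0 * np.log10(np.mean([s.mean(axis=0) for s in a], axis=0)
                                / np.mean([s.mean(axis=0) for s in b], axis=0))
    flagged = (lo > 0.0) | (hi < 0.0)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    min_run = int(np.ceil(resolution_hz / df))
    significant = np.zeros_like(flagged)
    k = 0
    while k < flagged.size:
        if flagged[k]:
            j = k
            while j < flagged.size and flagged[j]:
                j += 1
            if j - k > min_run:
                significant[k:j] = True
            k = j
        else:
            k += 1
    return BootstrapComparison(np.asarray(freqs), mean_diff, lo, hi, significant,
                               resolution_hz, n_boot)


@dataclass
class BandPowerComparison:
    per_electrode_db: pd.DataFrame  # subject, electrode, diff_db
    median_db: float
    ci: tuple[float, float]
    per_subject_p: dict


def band_power_compare(freqs, power_a, power_b, subjects,
                       band: tuple[float, float] = (10.0, 40.0),
                       n_boot: int = 1000, seed=0,
                       electrodes=None) -> BandPowerComparison:
    """Per-electrode band-power difference (a minus b, dB) across states.

    ``power_a``/``power_b`` are matched (n_electrodes, n_freq) linear-power
    spectra (same electrodes, e.g. emergence vs N2 sleep); ``subjects`` maps
    each electrode row to its subject. The per-electrode statistic is the
    mean over band frequencies of the per-frequency dB difference; the cohort
    median gets a pooled bootstrap CI and each subject a signed-rank test.
    """
    power_a, power_b = np.asarray(power_a), np.asarray(power_b)
    if power_a.shape != power_b.shape:
        raise ValueError("state spectra are not matched")
    m = (np.asarray(freqs) >= band[0]) & (np.asarray(freqs) <= band[1])
    diff = (10.0 * np.log10(power_a[:, m] / power_b[:, m])).mean(axis=1)
    subjects = np.asarray(subjects)
    if electrodes is None:
        electrodes = np.arange(diff.size)
    table = pd.DataFrame({"subject": subjects, "electrode": electrodes,
                          "diff_db": diff})
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(diff, size=(n_boot, diff.size), replace=True), axis=1)
    ci = tuple(float(v) for v in np.percentile(boots, [2.5, 97.5]))
    per_subject_p = {}
    for s in np.unique(subjects):
        d = diff[subjects == s]
        if d.size < 2 or np.allclose(d, 0.0):
            per_subject_p[s] = 1.0 if d.size >= 2 else float("nan")
        else:
            per_subject_p[s] = float(stats.wilcoxon(d).pvalue)
    return BandPowerComparison(table, float(np.median(diff)), ci, per_subject_p)


def ssaep_power(trials: Trials, channel: int = 0, f_target: float = 40.0,
                f_control: float = 22.0, stim_duration: float = 2.0,
                window_s: float = 60.0, n_tapers: int = 3) -> pd.DataFrame:
    """Induced power at the click frequency (and a control) per time window.

    For each click-train trial the multitaper power at the bin nearest the
    target / control frequency over the 2 s stimulation period is computed,
    minus the power at the same frequency over a matched-length pre-stimulus
    window (so state-dependent background shifts cancel and a frequency with
    no steady-state response reads ~0). Values are averaged over ``window_s``
    windows. Trials shorter than the stimulation period are skipped.
    """
    post = (trials.times >= 0.0) & (trials.times < stim_duration)
    pre = (trials.times >= -stim_duration) & (trials.times < 0.0)
    if post.sum() < int(stim_duration * trials.fs):
        raise ValueError("trials shorter than the stimulation period")
    n = min(post.sum(), pre.sum())
    freqs, psd_post = mt_psd(trials.data[:, channel, post][:, :n], trials.fs, n_tapers)
    _, psd_pre = mt_psd(trials.data[:, channel, pre][:, -n:], trials.fs, n_tapers)
    it = int(np.argmin(np.abs(freqs - f_target)))
    ic = int(np.argmin(np.abs(freqs - f_control)))
    tab = pd.DataFrame({"onset_s": trials.onsets,
                        "target_power": psd_post[:, it] - psd_pre[:, it],
                        "control_power": psd_post[:, ic] - psd_pre[:, ic]})
    if trials.stim_types is not None and len(trials.stim_types):
        tab = tab[np.asarray(trials.stim_types) == "click"]
    tab["window"] = (tab["onset_s"] // window_s).astype(int)
    agg = tab.groupby("window").agg(
        target_power=("target_power", "mean"),
        control_power=("control_power", "mean"),
        n_trials=("onset_s", "size")).reset_index()
    agg["window_center"] = (agg["window"] + 0.5) * window_s
    return agg[["window_center", "target_power", "control_power", "n_trials"]]
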