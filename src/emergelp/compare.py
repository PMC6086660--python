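"""Spatial-distribution statistics and sleep-vs-emergence event comparisons.

Covers the regional-proportion analysis (which anatomical regions carry
channels with >= 5 detected events, binomial test against the cohort mean
rate with Bonferroni correction), the cross-state spatial-profile correlation
(mean peak-triggered event value per channel, sleep vs emergence), and the
pooled amplitude-distribution comparison between sleep K-complexes and
emergence LPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectorParams, detect_lp_channel, enforce_polarity
from .preprocess import ChannelInfo, Recording

logger = logging.getLogger(__name__)


@dataclass
class RegionStats:
    region: str
    n_electrodes: int
    n_qualifying: int
    proportion: float
    p_value: float
    significant: bool  # Bonferroni-corrected, and above the mean rate


def region_proportions(events: pd.DataFrame, channels: list[ChannelInfo],
                       min_events: int = 5, min_electrodes: int = 6,
                       alpha: float = 0.05) -> list[RegionStats]:
    """Per-region proportions of channels with >= ``min_events`` events.

    Regions with fewer than ``min_electrodes`` electrodes (and channels with
    no region label, e.g. white matter) are excluded. Each retained region is
    compared to the pooled mean qualifying rate with a two-sided binomial
    test, Bonferroni-corrected over regions; the significance flag further
    requires the proportion to exceed the mean rate (the effect direction of
    interest).
    """
    counts = events.groupby("channel").size() if len(events) else pd.Series(dtype=int)
    rows = []
    for c in channels:
        if c.is_bad or c.region is None:
            continue
        rows.append((c.region, counts.get(c.name, 0) >= min_events))
    if not rows:
        return []
    tab = pd.DataFrame(rows, columns=["region", "qualifying"])
    sizes = tab.groupby("region").size()
    keep = sizes[sizes >= min_electrodes].index
    tab = tab[tab["region"].isin(keep)]
    if not len(tab):
        return []
    mean_rate = tab["qualifying"].mean()
    n_regions = tab["region"].nunique()
    out = []
    for region, grp in tab.groupby("region"):
        n, k = len(grp), int(grp["qualifying"].sum())
        p = stats.binomtest(k, n, mean_rate).pvalue if 0 < mean_rate < 1 else 1.0
        prop = k / n
        out.append(RegionStats(region=region, n_electrodes=n, n_qualifying=k,
                               proportion=prop, p_value=float(p),
                               significant=bool(p * n_regions < alpha
                                                and prop > mean_rate)))
    return sorted(out, key=lambda r: r.region)


@dataclass
class PairedStateResult:
    """Cross-state comparison keyed to matched channels."""

    channels: list[str]
    values_a: np.ndarray  # per-channel mean event value, state A (µV)
    values_b: np.ndarray
    correlation: float | None = None
    median_a: float | None = None
    median_b: float | None = None
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    rank_sum_p: float | None = None


def _mean_event_values(rec: Recording, peak_times, half_window: float) -> np.ndarray:
    """Per-channel mean signal value within ±half_window of the trigger peaks."""
    h = int(round(half_window * rec.fs))
    vals = np.zeros(rec.n_channels)
    count = 0
    for t in peak_times:
        c = int(round(t * rec.fs))
        if c - h < 0 or c + h + 1 > rec.samples.shape[1]:
            continue
        vals += rec.samples[:, c - h:c + h + 1].mean(axis=1)
        count += 1
    if count == 0:
        raise ValueError("no trigger events fit within the recording")
    return vals / count


def cross_state_spatial_correlation(rec_a: Recording, rec_b: Recording,
                                    trigger_channel: str,
                                    params: DetectorParams | None = None,
                                    half_window: float = 0.1,
                                    min_events: int = 20) -> PairedStateResult:
    """Spatial-profile correlation of events across two states.

    Events are detected on a single trigger channel in each recording (>= 20
    required in both); the per-channel mean value of the peak-triggered
    waveform within ±100 ms is compared across matched channels with a
    Pearson correlation.
    """
    if rec_a.channel_names != rec_b.channel_names:
        raise ValueError("recordings do not share a montage")
    params = params or DetectorParams()
    peaks = {}
    for label, rec in (("state_a", rec_a), ("state_b", rec_b)):
        ch = rec.channel_index(trigger_channel)
        ev, _ = enforce_polarity(detect_lp_channel(rec.samples[ch], rec.fs, params,
                                                   window=rec.analysis_window,
                                                   channel=trigger_channel))
        if len(ev) < min_events:
            raise ValueError(f"{label} has only {len(ev)} trigger events "
                             f"(needs {min_events})")
        peaks[label] = [e.peak_time for e in ev]
    va = _mean_event_values(rec_a, peaks["state_a"], half_window)
    vb = _mean_event_values(rec_b, peaks["state_b"], half_window)
    r = float(stats.pearsonr(va, vb).statistic)
    return PairedStateResult(channels=rec_a.channel_names, values_a=va, values_b=vb,
                             correlation=r)


def amplitude_distribution_compare(events_a: pd.DataFrame, events_b: pd.DataFrame,
                                   min_events_per_channel: int = 4,
                                   n_boot: int = 1000, seed=0) -> PairedStateResult:
    """Compare |event amplitude| distributions across two states.

    Channels with >= ``min_events_per_channel`` events in *both* tables are
    pooled (the tables carry ``subject``, ``channel`` and ``amplitude_uV``).
    Medians get bootstrap CIs drawn from the pooled events; the rank-sum test
    draws equal-sized subsamples from both states within each subject (one
    fixed seeded draw) so the test is not driven by unequal counts.
    """
    def counts(ev):
        return ev.groupby(["subject", "channel"]).size()

    ca, cb = counts(events_a), counts(events_b)
    shared = ca[ca >= min_events_per_channel].index.intersection(
        cb[cb >= min_events_per_channel].index)
    if not len(shared):
        raise ValueError("no channels qualify in both states")

    def pooled(ev):
        key = pd.MultiIndex.from_frame(ev[["subject", "channel"]])
        return ev.loc[key.isin(shared)]

    ea, eb = pooled(events_a), pooled(events_b)
    amp_a = np.abs(ea["amplitude_uV"].to_numpy())
    amp_b = np.abs(eb["amplitude_uV"].to_numpy())
    rng = np.random.default_rng(seed)

    def med_ci(v):
        boots = np.median(rng.choice(v, size=(n_boot, v.size), replace=True), axis=1)
        return float(np.median(v)), tuple(float(x) for x in np.percentile(boots, [2.5, 97.5]))

    med_a, ci_a = med_ci(amp_a)
    med_b, ci_b = med_ci(amp_b)
    sub_a, sub_b = [], []
    for s in sorted(set(ea["subject"]) & set(eb["subject"])):
        va = np.abs(ea.loc[ea["subject"] == s, "amplitude_uV"].to_numpy())
        vb = np.abs(eb.loc[eb["subject"] == s, "amplitude_uV"].to_numpy())
        m = min(va.size, vb.size)
        sub_a.append(rng.choice(va, size=m, replace=False))
        sub_b.append(rng.choice(vb, size=m, replace=False))
    p = float(stats.ranksums(np.concatenate(sub_a), np.concatenate(sub_b)).pvalue)
    chans = [f"{s}/{c}" for s, c in shared]
    return PairedStateResult(channels=chans, values_a=amp_a, values_b=amp_b,
                             median_a=med_a, median_b=med_b, ci_a=ci_a, ci_b=ci_b,
                             rank_sum_p=p)
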