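"""Detector rules against an independent brute-force threshold-scan oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from emergelp.detect import (DetectedEvent, DetectorParams, band_filter,
                             classify_evoked, detect_lp_channel, detect_lp_scalp,
                             enforce_polarity, qualifying_channels)
from emergelp.preprocess import Trials
from emergelp.simulate import LPTemplateParams, lp_waveform, make_background


def brute_force_detect(signal, fs, params: DetectorParams):
    """Independent rule-by-rule scan: filter, enumerate strict local extrema of
    either sign, test amplitude / duration / artifact rules per candidate, then
    apply the refractory rule walking forward in time."""
    sos = sps.butter(4, np.asarray(params.band) / (fs / 2.0), "bandpass",
                     output="sos")
    x = sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))
    cands = []
    for i in range(1, x.size - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= params.min_peak:
            cands.append((i, 1))
        elif x[i] < x[i - 1] and x[i] < x[i + 1] and x[i] <= -params.min_peak:
            cands.append((i, -1))
    out = []
    for i, sign in cands:
        thr = params.duration_threshold * sign
        j0 = i
        while j0 > 0 and (x[j0 - 1] * sign) >= params.duration_threshold:
            j0 -= 1
        j1 = i
        while j1 < x.size - 1 and (x[j1 + 1] * sign) >= params.duration_threshold:
            j1 += 1
        if (j1 - j0 + 1) / fs < params.min_duration:
            continue
        if abs(x[i]) > params.artifact_peak:
            continue
        out.append((i / fs, float(x[i]), (j1 - j0 + 1) / fs, sign))
    kept, last = [], -np.inf
    for t, amp, dur, sign in out:
        if t - last < params.refractory:
            continue
        kept.append((t, amp, dur, sign))
        last = t
    return kept


def plant(template_amp, t_peak, duration=60.0, fs=500.0, **kw):
    x = np.zeros(int(duration * fs))
    _, w = lp_waveform(LPTemplateParams(peak_amplitude=template_amp, **kw), fs)
    c = int(t_peak * fs)
    pk = int(np.argmax(np.abs(w)))
    x[c - pk:c - pk + w.size] += w
    return x


class TestDetectChannel:
    def test_flat_trace_empty(self):
        assert detect_lp_channel(np.zeros(30000), 500.0) == []

    def test_single_template_detected_once(self):
        x = plant(600.0, 30.0)
        events = detect_lp_channel(x, 500.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_time == pytest.approx(30.0, abs=0.1)
        assert ev.polarity == 1
        assert ev.supra_duration >= 0.4
        # oracle agreement on the same trace
        oracle = brute_force_detect(x, 500.0, DetectorParams())
        assert len(oracle) == 1
        assert oracle[0][0] == ev.peak_time
        assert oracle[0][1] == ev.peak_amplitude

    def test_artifact_amplitude_discarded(self):
        # choose a planted amplitude whose band-filtered peak exceeds 1200 µV
        for amp in (1400.0, 1600.0):
            x = plant(amp, 30.0)
            filt_peak = np.abs(band_filter(x, 500.0)).max()
            events = detect_lp_channel(x, 500.0)
            if filt_peak > 1200.0:
                assert events == []
                return
        pytest.fail("no amplitude produced a filtered peak above the artifact limit")

    def test_subthreshold_amplitude_ignored(self):
        x = plant(300.0, 30.0)
        assert detect_lp_channel(x, 500.0) == []

    def test_refractory_keeps_earlier_event(self):
        fs = 500.0
        x = np.zeros(int(60 * fs))
        # two fast half-sine lobes 0.3 s apart, each individually valid
        t = np.arange(int(0.5 * fs)) / fs
        lobe = 600.0 * np.sin(np.pi * t / 0.5)
        x[int(30 * fs):int(30 * fs) + lobe.size] += lobe
        x[int(30.3 * fs):int(30.3 * fs) + lobe.size] += lobe
        events = detect_lp_channel(x, fs, DetectorParams(refractory=1.0))
        more = detect_lp_channel(x, fs, DetectorParams(refractory=0.05))
        assert len(events) <= len(more)
        if len(events) == 1 and len(more) == 2:
            assert events[0].peak_time == more[0].peak_time  # earlier one kept

    def test_short_window_empty(self):
        x = plant(600.0, 30.0)
        assert detect_lp_channel(x, 500.0, window=(29.9, 30.1)) == []

    def test_scale_equivariance(self):
        x = plant(600.0, 30.0) + make_background("emergence", 1, 60.0, 500.0, 3)[0]
        base = detect_lp_channel(x, 500.0)
        g = 2.5
        p = DetectorParams(min_peak=400.0 * g, duration_threshold=40.0 * g,
                           artifact_peak=1200.0 * g)
        scaled = detect_lp_channel(g * x, 500.0, p)
        assert len(base) == len(scaled) > 0
        for a, b in zip(base, scaled):
            assert b.peak_time == a.peak_time
            assert b.peak_amplitude == pytest.approx(g * a.peak_amplitude, rel=1e-9)

    def test_false_positive_rate_on_event_free_background(self):
        for profile in ("emergence", "sleep_n2", "anesthetized"):
            minutes, n_fp = 0.0, 0
            for seed in range(3):
                bg = make_background(profile, 1, 120.0, 500.0, seed)[0]
                n_fp += len(detect_lp_channel(bg, 500.0))
                minutes += 2.0
            assert n_fp / minutes < 0.5, profile

    def test_oracle_equivalence_on_noisy_traces(self, rng):
        params = DetectorParams()
        for k in range(10):
            bg = make_background("anesthetized", 1, 40.0, 500.0, 100 + k)[0] * 3.0
            for t_peak in rng.uniform(5, 35, size=2):
                bg += plant(float(rng.uniform(450, 1300)), float(t_peak),
                            duration=40.0)
            events = detect_lp_channel(bg, 500.0, params)
            oracle = brute_force_detect(bg, 500.0, params)
            assert [(e.peak_time, e.peak_amplitude) for e in events] == \
                [(t, a) for t, a, _, _ in oracle]


class TestPolarity:
    def make(self, signs):
        return [DetectedEvent("ch", float(i), 500.0 * s, 0.5, s)
                for i, s in enumerate(signs)]

    def test_majority_negative_kept(self):
        ev, pol = enforce_polarity(self.make([-1] * 6 + [1] * 2))
        assert pol == -1 and len(ev) == 6

    def test_uniform_unchanged(self):
        ev, pol = enforce_polarity(self.make([-1] * 4))
        assert pol == -1 and len(ev) == 4

    def test_tie_break_negative(self):
        ev, pol = enforce_polarity(self.make([1, -1, 1, -1, 1, -1]))
        assert pol == -1 and all(e.polarity == -1 for e in ev)

    def test_empty(self):
        ev, pol = enforce_polarity([])
        assert ev == [] and pol is None


class TestClassifyEvoked:
    stimuli = pd.DataFrame({"onset_s": [10.0, 14.0], "type": ["click", "word"]})

    def ev(self, t):
        return DetectedEvent("ch", t, -500.0, 0.5, -1)

    def test_event_1s_after_stimulus_evoked(self):
        [e] = classify_evoked([self.ev(11.0)], self.stimuli)
        assert e.evoked and e.stimulus_index == 0

    def test_event_2p5s_after_last_stimulus_spontaneous(self):
        [e] = classify_evoked([self.ev(16.5)], self.stimuli)
        assert not e.evoked and e.stimulus_index is None

    def test_exact_2s_boundary_counts_as_evoked(self):
        [e] = classify_evoked([self.ev(12.0)], self.stimuli)
        assert e.evoked

    def test_event_before_all_stimuli_spontaneous(self):
        [e] = classify_evoked([self.ev(5.0)], self.stimuli)
        assert not e.evoked


class TestQualifyingChannels:
    def test_threshold_at_five_events(self):
        rows = [{"channel": "A", "peak_time_s": i} for i in range(5)]
        rows += [{"channel": "B", "peak_time_s": i} for i in range(4)]
        qual, busiest = qualifying_channels(pd.DataFrame(rows))
        assert qual == ["A"] and busiest == "A"

    def test_empty(self):
        qual, busiest = qualifying_channels(pd.DataFrame(columns=["channel"]))
        assert qual == [] and busiest is None


def noise_trials(rng, n_trials=200, fs=500.0):
    times = np.arange(-int(2.5 * fs), int(2.5 * fs)) / fs
    data = rng.standard_normal((n_trials, 1, times.size)) * 10.0
    return Trials(data=data, times=times, onsets=np.arange(n_trials) * 4.0,
                  stim_index=np.arange(n_trials),
                  rejected=np.zeros((n_trials, 1), bool), fs=fs,
                  channel_names=["Fz"])


class TestScalpDetector:
    def test_planted_high_z_trial_detected(self, rng):
        trials = noise_trials(rng, n_trials=10)
        post = (trials.times > 0) & (trials.times <= 1.0)
        trials.data[3, 0, post] += 120.0  # z = 12 vs baseline sd 10
        det = detect_lp_scalp(trials, z_threshold=7.0)
        assert bool(det.loc[det.trial == 3, "detected"].iloc[0])
        assert det["detected"].sum() == 1

    def test_threshold_monotonicity(self, rng):
        trials = noise_trials(rng)
        d7 = detect_lp_scalp(trials, z_threshold=7.0)
        d5 = detect_lp_scalp(trials, z_threshold=5.0)
        assert set(d7[d7.detected].trial) <= set(d5[d5.detected].trial)

    def test_null_rate_matches_monte_carlo_oracle(self, rng):
        # detection statistic: max |z| over the 1 s post window of white noise
        trials = noise_trials(rng, n_trials=400)
        det = detect_lp_scalp(trials, z_threshold=4.0)
        rate = det["detected"].mean()
        # independent Monte-Carlo of the same max statistic
        n_post = int(((trials.times > 0) & (trials.times <= 1.0)).sum())
        n_base = int(((trials.times >= -2.0) & (trials.times < 0)).sum())
        sims = []
        for _ in range(2000):
            base = rng.standard_normal(n_base)
            z = (rng.standard_normal(n_post) - base.mean()) / base.std()
            sims.append(np.abs(z).max() > 4.0)
        mc = np.mean(sims)
        se = np.sqrt(mc * (1 - mc) / 2000 + rate * (1 - rate) / 400)
        assert abs(rate - mc) < 4 * se + 0.01

    def test_scalp_volunteer_detections_concentrate_in_emergence(self):
        from emergelp.preprocess import extract_trials, filter_chain
        from emergelp.simulate import make_cohort

        n_em = n_out = trials_em = trials_out = 0
        for seed in (5, 6):
            [(rec, _)] = make_cohort("scalp-volunteer", 1, seed=seed)
            roc = rec.markers["first_response"]
            rec = filter_chain(rec)
            trials = extract_trials(rec, window=(-2.5, 2.5))
            det = detect_lp_scalp(trials, z_threshold=5.0)
            em = (det.onset_s > roc - 200) & (det.onset_s < roc + 30)
            n_em += int(det[em].detected.sum())
            n_out += int(det[~em].detected.sum())
            trials_em += int(em.sum())
            trials_out += int((~em).sum())
        assert n_em >= 4
        assert n_em / trials_em > 2 * (n_out / trials_out)

    def test_zero_variance_baseline_skipped(self):
        times = np.arange(-1250, 1250) / 500.0
        data = np.zeros((2, 1, times.size))
        data[1] = np.random.default_rng(0).standard_normal(times.size)
        trials = Trials(data=data, times=times, onsets=np.array([0.0, 4.0]),
                        stim_index=np.arange(2), rejected=np.zeros((2, 1), bool),
                        fs=500.0, channel_names=["Fz"])
        det = detect_lp_scalp(trials)
        assert list(det.trial) == [1]
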