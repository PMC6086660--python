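"""Generator contracts: template morphology, backgrounds, trains, ledgers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emergelp.erp import rise_fall_times
from emergelp.simulate import (DEFAULT_PROFILES, LPTemplateParams, SessionConfig,
                               lp_waveform, make_background, make_cohort,
                               make_session, make_stimulus_train)
from emergelp.spectral import SpectralParams, epoch_spectrum


class TestLPWaveform:
    def test_amplitude_normalization(self):
        t, w = lp_waveform(LPTemplateParams(peak_amplitude=550.0), 500.0)
        assert np.abs(w).max() == pytest.approx(550.0)
        assert t[np.argmax(np.abs(w))] == 0.0

    def test_default_rise_fall_measured_at_200uv(self):
        t, w = lp_waveform(LPTemplateParams(), 500.0)
        rise, fall = rise_fall_times(w, 200.0, t)
        assert rise == pytest.approx(165.0, rel=0.02)
        assert fall == pytest.approx(285.0, rel=0.02)
        assert rise < fall

    def test_symmetric_params_give_symmetric_times(self):
        p = LPTemplateParams(rise_time=220, fall_time=220, rebound_fraction=0.0)
        t, w = lp_waveform(p, 500.0)
        rise, fall = rise_fall_times(w, 200.0, t)
        assert rise == pytest.approx(fall, abs=3.0)

    def test_supra_threshold_duration_exceeds_400ms(self):
        t, w = lp_waveform(LPTemplateParams(), 500.0)
        i = int(np.argmax(np.abs(w)))
        run = np.abs(w) >= 40.0
        j0 = i
        while j0 > 0 and run[j0 - 1]:
            j0 -= 1
        j1 = i
        while j1 < w.size - 1 and run[j1 + 1]:
            j1 += 1
        assert (j1 - j0 + 1) / 500.0 > 0.4

    def test_rebound_has_opposite_sign(self):
        _, w = lp_waveform(LPTemplateParams(), 500.0)
        assert w.min() < -0.1 * np.abs(w).max()

    @pytest.mark.parametrize("kwargs", [{"peak_amplitude": -10.0},
                                        {"rise_time": 0.0}, {"fall_time": -5.0}])
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            lp_waveform(LPTemplateParams(**kwargs), 500.0)

    def test_invalid_fs_raises(self):
        with pytest.raises(ValueError):
            lp_waveform(LPTemplateParams(), 0.0)


class TestBackground:
    def test_deterministic_given_seed(self):
        a = make_background("emergence", 3, 5.0, 500.0, 7)
        b = make_background("emergence", 3, 5.0, 500.0, 7)
        np.testing.assert_array_equal(a, b)
        c = make_background("emergence", 3, 5.0, 500.0, 8)
        assert not np.array_equal(a, c)

    def test_unknown_profile_raises(self):
        with pytest.raises(ValueError):
            make_background("rem_sleep", 2, 5.0, 500.0, 0)

    def test_sleep_spectrum_has_spindle_peak(self):
        sig = make_background("sleep_n2", 1, 180.0, 500.0, 11)[0]
        res = epoch_spectrum(sig, 500.0, SpectralParams())
        band = (res.freqs >= 10) & (res.freqs <= 14)
        flank = ((res.freqs >= 16) & (res.freqs <= 20))
        assert res.values[band].max() > res.values[flank].max() + 2.0

    def test_emergence_sleep_band_offset_matches_profile(self):
        # same seed family, 10-40 Hz dB difference ~ configured 5.6 dB shelf
        e = make_background("emergence", 1, 180.0, 500.0, 21)[0]
        s = make_background("sleep_n2", 1, 180.0, 500.0, 21)[0]
        pe = epoch_spectrum(e, 500.0, SpectralParams())
        ps = epoch_spectrum(s, 500.0, SpectralParams())
        band = (pe.freqs >= 12) & (pe.freqs <= 38)  # inside the shelf, off edges
        diff = np.median(pe.values[band] - ps.values[band])
        assert diff == pytest.approx(DEFAULT_PROFILES["emergence"].shelf_db, abs=1.0)

    def test_frontal_channels_receive_alpha(self):
        sig = make_background("anesthetized", 2, 180.0, 500.0, 5,
                              frontal_mask=[True, False])
        pf = epoch_spectrum(sig[0], 500.0, SpectralParams())
        pn = epoch_spectrum(sig[1], 500.0, SpectralParams())
        band = (pf.freqs >= 9) & (pf.freqs <= 11)
        assert np.median(pf.values[band] - pn.values[band]) > 3.0


class TestStimulusTrain:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(duration=st.floats(30.0, 400.0), seed=st.integers(0, 10 ** 6))
    def test_jitter_isis_in_bounds(self, duration, seed):
        tab = make_stimulus_train(duration, "jitter_3.5_4.5", seed=seed)
        onsets = tab["onset_s"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        if len(onsets) > 1:
            isi = np.diff(onsets)
            assert isi.min() >= 3.5 and isi.max() <= 4.5

    def test_fixed_mode_isis(self):
        tab = make_stimulus_train(100.0, "fixed_6", seed=0)
        np.testing.assert_allclose(np.diff(tab["onset_s"]), 6.0)

    def test_type_mix_within_binomial_bounds(self):
        mix = {"click": 0.8, "word": 0.1, "name": 0.1}
        tab = make_stimulus_train(4100.0, type_mix=mix, seed=1)
        n = len(tab)
        assert n > 900
        for typ, p in mix.items():
            k = int((tab["type"] == typ).sum())
            # 4-sigma binomial bound
            assert abs(k - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError):
            make_stimulus_train(60.0, type_mix={"click": 0.5, "word": 0.2}, seed=0)

    def test_short_duration_gives_empty_table(self):
        assert len(make_stimulus_train(8.0, seed=0)) == 0

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            make_stimulus_train(60.0, isi_mode="poisson", seed=0)


class TestMakeSession:
    def test_no_events_when_probabilities_zero(self):
        cfg = SessionConfig(seed=1, evoked_probability=0.0,
                            evoked_probability_out=0.0,
                            spontaneous_fraction=0.0, min_events=0)
        _, gt = make_session(cfg)
        assert gt.n_events == 0

    def test_ledger_events_visible_in_signal(self, emergence_session):
        rec, gt = emergence_session
        fs = rec.fs
        for _, ev in gt.events.head(5).iterrows():
            c = int(round(ev.peak_time_s * fs))
            seg = rec.samples[0, c - 100:c + 100]
            assert np.abs(seg).max() > 0.6 * ev.amplitude_uV

    def test_determinism(self):
        cfg = SessionConfig(seed=99, duration=120.0, n_channels=4)
        r1, g1 = make_session(cfg)
        r2, g2 = make_session(SessionConfig(seed=99, duration=120.0, n_channels=4))
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert g1.events.equals(g2.events)

    def test_evoked_events_within_2s_of_stimulus(self, emergence_session):
        rec, gt = emergence_session
        onsets = rec.stimuli["onset_s"].to_numpy()
        ev = gt.events[gt.events.evoked]
        lat = ev.peak_time_s.to_numpy() - onsets[ev.stimulus_index.to_numpy()]
        assert np.all((lat > 0) & (lat <= 2.0))

    def test_marker_validation(self):
        with pytest.raises(ValueError):
            SessionConfig(duration=100.0, markers={"first_response": 150.0},
                          state_timeline=[("emergence", 0.0, 100.0)])


class TestMakeCohort:
    def test_emergence_cohort_guarantees_events(self):
        cohort = make_cohort("paper-emergence", 3, seed=5)
        assert len(cohort) == 3
        for _, gt in cohort:
            assert gt.n_events >= 5

    def test_sleep_pair_shares_spatial_profile(self):
        pairs = make_cohort("paper-sleep-pair", 2, seed=6)
        for pair in pairs:
            np.testing.assert_array_equal(pair.sleep[1].spatial_profile,
                                          pair.emergence[1].spatial_profile)
            np.testing.assert_array_equal(pair.sleep[1].polarity,
                                          pair.emergence[1].polarity)
            np.testing.assert_array_equal(pair.sleep[1].channel_offsets,
                                          pair.emergence[1].channel_offsets)

    def test_cohort_determinism(self):
        a = make_cohort("paper-emergence", 2, seed=7)
        b = make_cohort("paper-emergence", 2, seed=7)
        for (_, ga), (_, gb) in zip(a, b):
            assert ga.events.equals(gb.events)

    def test_induction_sessions_lack_transitional_events(self):
        # the transitional LP state is selective to emergence: gradual
        # induction sessions plant essentially no events
        cohort = make_cohort("paper-induction", 3, seed=8)
        assert all(gt.n_events < 5 for _, gt in cohort)
        assert sum(gt.n_events for _, gt in cohort) < 10

    def test_scalp_events_are_word_or_name_evoked(self):
        [(rec, gt)] = make_cohort("scalp-volunteer", 1, seed=9)
        ev = gt.events[gt.events.evoked]
        types = rec.stimuli["type"].to_numpy()[ev.stimulus_index.to_numpy()]
        assert set(types) <= {"word", "name"}

    def test_unknown_profile_raises(self):
        with pytest.raises(ValueError):
            make_cohort("paper-rem", 1, seed=0)

    def test_n_sessions_validation(self):
        with pytest.raises(ValueError):
            make_cohort("paper-emergence", 0, seed=0)
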