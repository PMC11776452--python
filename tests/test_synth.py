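"""Synthetic-audience generator: point-process correctness, determinism,
orienting geometry, and render/detect round trips."""
import numpy as np
import pytest

from cardiosync.features import spectral_flux
from cardiosync.prep import RawRecording, detect_r_peaks, detect_resp_peaks, filter_physio
from cardiosync.series import PeakSeries
from cardiosync.synth import (
    ParticipantSpec,
    StimulusSpec,
    generate_audience,
    generate_stimulus,
    orienting_waveform,
    participant_rate,
    peaks_from_rate,
    render_waveforms,
)


def make_spec(**kw):
    defaults = dict(participant_id="p1", seed=1)
    defaults.update(kw)
    return ParticipantSpec(**defaults)


class TestStimulus:
    def test_constant_tone_has_no_flux_after_onset(self):
        spec = StimulusSpec(
            duration_s=20.0, tone_schedule=[(2.0, 440.0, 0.5)], piece_id="x"
        )
        wave, _ = generate_stimulus(spec)
        fl = spectral_flux(wave, spec.sample_rate_hz)
        onset_frame = int(round(2.0 / fl.frame_hop_s))
        assert fl.flux[onset_frame + 4 :].max() < 0.01 * fl.flux.max()

    def test_amplitude_step_puts_flux_peak_at_step(self):
        spec = StimulusSpec(
            duration_s=20.0,
            tone_schedule=[(0.0, 440.0, 0.25), (10.0, 440.0, 0.9)],
        )
        wave, _ = generate_stimulus(spec)
        fl = spectral_flux(wave, spec.sample_rate_hz)
        t_peak = fl.frame_times_s[np.argmax(fl.flux)]
        assert abs(t_peak - 10.0) <= 2 * fl.frame_hop_s

    def test_empty_schedule_is_silence(self):
        spec = StimulusSpec(duration_s=10.0)
        wave, _ = generate_stimulus(spec)
        assert np.all(wave == 0)
        assert np.all(spectral_flux(wave, spec.sample_rate_hz).flux == 0)

    def test_duplicate_onsets_rejected(self):
        with pytest.raises(ValueError, match="identical onsets"):
            StimulusSpec(
                duration_s=10.0,
                tone_schedule=[(1.0, 440.0, 0.5), (1.0, 660.0, 0.5)],
            )


class TestPointProcess:
    def test_constant_rate_gives_exact_intervals(self):
        times = peaks_from_rate(np.full(50 * 180 + 1, 60.0), 1 / 50, 180.0)
        assert times.size == 180  # floor(duration) peaks at 60 BPM
        assert np.allclose(np.diff(times), 1.0, atol=1e-9)

    def test_constant_spec_audience_has_unit_ibis(self):
        spec = make_spec(
            base_heart_hz=1.0, coupling_gain=0.0, orienting_depth_bpm=0.0, noise_sd_bpm=0.0
        )
        records, _ = generate_audience(60.0, [spec, make_spec(participant_id="p2", base_heart_hz=1.0, coupling_gain=0.0, orienting_depth_bpm=0.0, noise_sd_bpm=0.0)], "AO")
        ibis = records[0]["heart"].intervals_s
        assert np.allclose(ibis, 1.0, atol=1e-9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            peaks_from_rate(np.array([60.0, -1.0, 60.0]), 0.02, 1.0)

    def test_identical_seeds_give_identical_trains(self):
        kw = dict(coupling_gain=0.0, orienting_depth_bpm=0.0, seed=42)
        a = make_spec(participant_id="a", **kw)
        b = make_spec(participant_id="b", **kw)
        records, _ = generate_audience(60.0, [a, b], "AO")
        assert np.array_equal(
            records[0]["heart"].times_s, records[1]["heart"].times_s
        )
        assert np.array_equal(records[0]["resp"].times_s, records[1]["resp"].times_s)

    def test_lag_must_stay_within_one_cycle(self):
        with pytest.raises(ValueError, match="cardiac cycle"):
            make_spec(lag_ms=1200.0)


class TestOrienting:
    def test_boundary_window_rate_is_lower_than_flanks(self):
        # oracle: integrate the specified rate function directly
        t = np.arange(0.0, 120.0, 0.02)
        rate = 60.0 + orienting_waveform(t, [60.0], 0.5)
        win = lambda c: rate[(t >= c - 3) & (t < c + 3)].mean()
        assert win(60.0) < win(50.0)
        assert win(60.0) < win(70.0)
        # oracle: mean of the half-sine deceleration lobe over [-3, 3] s
        expected = 0.5 * (10 / (6 * np.pi)) * (np.cos(0.2 * np.pi) - np.cos(0.8 * np.pi))
        assert win(50.0) - win(60.0) == pytest.approx(expected, rel=0.02)

    def test_orienting_only_in_enabled_condition(self):
        spec = make_spec(coupling_gain=0.0, noise_sd_bpm=0.0, orienting_depth_bpm=0.5)
        t = np.arange(0.0, 120.0, 0.02)
        r_av = participant_rate(t, spec, None, [60.0], "heart", True)
        r_ao = participant_rate(t, spec, None, [60.0], "heart", False)
        assert r_av.min() < spec.base_heart_hz * 60 - 0.4
        assert np.allclose(r_ao, spec.base_heart_hz * 60)


class TestRendering:
    def test_ecg_round_trip_recovers_all_peaks(self, quiet_audience):
        heart = quiet_audience[0]["heart"]
        resp = quiet_audience[0]["resp"]
        ecg, _ = render_waveforms(heart, resp, seed=3)
        rec = filter_physio(RawRecording(ecg, 1000.0, "heart"))
        detected = detect_r_peaks(rec)
        # recall 1.0 with every recovered time within 10 ms
        assert len(detected) == len(heart)
        assert np.abs(detected.times_s - heart.times_s).max() <= 0.010

    def test_resp_round_trip(self, quiet_audience):
        heart = quiet_audience[0]["heart"]
        resp = quiet_audience[0]["resp"]
        _, belt = render_waveforms(heart, resp, seed=3)
        rec = filter_physio(RawRecording(belt, 1000.0, "resp"))
        detected = detect_resp_peaks(rec)
        inner = resp.times_s[(resp.times_s > 5) & (resp.times_s < 115)]
        matched = [np.abs(detected.times_s - t).min() for t in inner]
        assert max(matched) <= 0.120

    def test_resp_render_peaks_are_local_maxima(self):
        heart = PeakSeries(np.arange(1.0, 30.0), 30.0)
        resp = PeakSeries(np.arange(2.0, 29.0, 3.4), 30.0)
        _, belt = render_waveforms(heart, resp, noise_sd=0.0, seed=0)
        for t in resp.times_s:
            i = int(round(t * 1000))
            lo, hi = max(i - 1500, 0), min(i + 1500, belt.size)
            assert belt[i] >= belt[lo:hi].max() - 1e-9

    def test_empty_peak_train_renders_noise_only(self):
        empty = PeakSeries(np.array([]), 30.0)
        resp = PeakSeries(np.arange(2.0, 29.0, 3.4), 30.0)
        ecg, _ = render_waveforms(empty, resp, seed=1)
        rec = filter_physio(RawRecording(ecg, 1000.0, "heart"))
        with pytest.warns(UserWarning, match="QRS"):
            detected = detect_r_peaks(rec)
        assert len(detected) == 0
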