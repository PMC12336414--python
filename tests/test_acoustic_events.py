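import numpy as np
import pandas as pd
import pytest
from scipy import signal as sg

from burrowcall.acoustic_events import (
    DEFAULT_SPECS,
    SAMPLE_RATE,
    AttenuationModel,
    AudioClip,
    CallTypeSpec,
    DetectionRanges,
    apply_detection_range,
    detect_calls,
    detect_calls_chunked,
    estimate_detection_range,
    read_wav,
    render_plot_night,
    synthesize_call,
    write_wav,
)


def band_fraction(clip, freq_lo, freq_hi):
    """FFT oracle: fraction of spectral power inside [freq_lo, freq_hi]."""
    f, p = sg.periodogram(clip.samples.astype(float), fs=clip.sample_rate)
    total = p[f >= 100].sum()
    return p[(f >= freq_lo) & (f <= freq_hi)].sum() / total


def spectral_centroid(clip):
    f, p = sg.periodogram(clip.samples.astype(float), fs=clip.sample_rate)
    return float((f * p).sum() / p.sum())


class TestCallTypeSpec:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(freq_lo=3000, freq_hi=300),  # inverted band
            dict(freq_hi=9000),  # above Nyquist
            dict(dur_lo=2.0, dur_hi=1.0),
            dict(n_syllables=0),
            dict(n_syllables=1),  # gap present but single syllable
        ],
    )
    def test_invariant_violations_rejected(self, bad):
        base = dict(
            call_type="adult_purr",
            freq_lo=300.0,
            freq_hi=3000.0,
            dur_lo=1.0,
            dur_hi=2.0,
            n_syllables=2,
            gap_lo=0.02,
            gap_hi=0.05,
        )
        base.update(bad)
        with pytest.raises(ValueError):
            CallTypeSpec(**base)

    def test_default_table_parameters(self):
        purr = DEFAULT_SPECS["adult_purr"]
        assert (purr.freq_lo, purr.freq_hi) == (300.0, 3000.0)
        assert purr.n_syllables == 2 and purr.gap_hi <= 0.05
        chat = DEFAULT_SPECS["adult_chat"]
        assert chat.n_syllables == 3 and (chat.gap_lo, chat.gap_hi) == (0.1, 0.3)
        beg = DEFAULT_SPECS["chick_beg"]
        assert (beg.freq_lo, beg.freq_hi) == (2600.0, 4000.0)
        assert beg.n_syllables == 1 and beg.gap_lo is None


class TestSynthesize:
    @pytest.mark.parametrize("name", list(DEFAULT_SPECS))
    def test_voiced_duration_syllables_and_gaps_within_spec(self, name):
        spec = DEFAULT_SPECS[name]
        for seed in range(5):
            clip = synthesize_call(spec, seed=seed)
            meta = clip.meta
            assert spec.dur_lo <= meta["voiced_s"] <= spec.dur_hi
            assert len(meta["syllable_bounds_s"]) == spec.n_syllables
            for g in meta["gaps_s"]:
                assert spec.gap_lo <= g <= spec.gap_hi

    def test_chick_energy_concentrated_in_beg_band(self):
        clip = synthesize_call(DEFAULT_SPECS["chick_beg"], seed=1)
        assert band_fraction(clip, 2600, 4000) > 0.9

    def test_purr_has_two_syllables_with_short_gap(self):
        clip = synthesize_call(DEFAULT_SPECS["adult_purr"], seed=2)
        assert len(clip.meta["gaps_s"]) == 1
        assert clip.meta["gaps_s"][0] < 0.05
        # the gap is an audible energy dip in the waveform
        (b0, b1), (b2, _) = clip.meta["syllable_bounds_s"]
        i0, i1 = int(b1 * SAMPLE_RATE), int(b2 * SAMPLE_RATE)
        gap_rms = np.sqrt(np.mean(clip.samples[i0:i1] ** 2)) if i1 > i0 else 0.0
        voiced_rms = np.sqrt(np.mean(clip.samples[: int(b1 * SAMPLE_RATE)] ** 2))
        assert gap_rms < 0.5 * voiced_rms

    def test_chat_centroid_inside_band(self):
        clip = synthesize_call(DEFAULT_SPECS["adult_chat"], seed=3)
        assert 200 <= spectral_centroid(clip) <= 6000

    def test_non_finite_audio_rejected(self):
        with pytest.raises(ValueError):
            AudioClip(np.array([0.0, np.nan]))


class TestRender:
    def test_zero_events_gives_pure_noise(self):
        clip = render_plot_night(pd.DataFrame(), seed=1, duration_s=10.0)
        assert clip.duration_s == pytest.approx(10.0, abs=0.01)
        rms = np.sqrt(np.mean(clip.samples.astype(float) ** 2))
        assert rms == pytest.approx(10 ** (-40 / 20), rel=0.05)

    def test_attenuation_monotone_with_distance(self, single_call_events):
        near = render_plot_night(
            single_call_events("adult_purr", 2.0, 1.5), seed=5, duration_s=6.0
        )
        far = render_plot_night(
            single_call_events("adult_purr", 40.0, 1.5), seed=5, duration_s=6.0
        )
        seg = slice(int(3.0 * SAMPLE_RATE), int(4.4 * SAMPLE_RATE))
        rms = lambda c: np.sqrt(np.mean(c.samples[seg].astype(float) ** 2))
        assert rms(near) > rms(far)

    def test_amplitude_model_decreases_in_distance(self):
        atten = AttenuationModel()
        d = np.arange(0, 50, 5)
        amps = [atten.amplitude("adult_chat", x) for x in d]
        assert all(a > b for a, b in zip(amps, amps[1:]))


class TestDetect:
    def test_silence_yields_nothing(self):
        clip = AudioClip(np.zeros(SAMPLE_RATE * 5, dtype=np.float32))
        events, seconds = detect_calls(clip)
        assert len(events) == 0
        assert all(v == 0.0 for v in seconds.values())

    def test_close_range_purrs_recovered_without_chick_confusion(self):
        rng = np.random.default_rng(11)
        rows, t = [], 2.0
        for _ in range(20):
            d = rng.uniform(1.0, 2.0)
            rows.append(
                dict(call_type="adult_purr", start_s=t, duration_s=d, position_m=3.0)
            )
            t += d + rng.uniform(1.0, 2.0)
        clip = render_plot_night(pd.DataFrame(rows), seed=12, duration_s=t + 2)
        events, _ = detect_calls(clip)
        assert (events["call_type"] == "adult_purr").sum() >= 18
        assert (events["call_type"] == "chick_beg").sum() == 0

    def test_tone_burst_in_chick_band_classified_chick(self):
        rng = np.random.default_rng(3)
        tt = np.arange(int(0.3 * SAMPLE_RATE)) / SAMPLE_RATE
        burst = np.sin(2 * np.pi * 3000 * tt) * sg.windows.tukey(len(tt), 0.1) * 0.05
        noise = rng.standard_normal(SAMPLE_RATE) * 0.01
        x = np.concatenate([noise, burst, noise]).astype(np.float32)
        events, _ = detect_calls(AudioClip(x))
        assert list(events["call_type"]) == ["chick_beg"]

    def test_detected_seconds_match_scene_truth(self, labelled_scene):
        events, clip = labelled_scene
        detected, seconds = detect_calls(clip)
        for ct in DEFAULT_SPECS:
            truth = events.loc[events["call_type"] == ct, "duration_s"].sum()
            assert seconds[ct] == pytest.approx(truth, rel=0.15)
        assert sum(seconds.values()) <= clip.duration_s

    def test_chunked_detection_independent_of_chunking(self, labelled_scene):
        _, clip = labelled_scene
        x = clip.samples

        def chunks(size_s, pad_s=3.0):
            size = int(size_s * SAMPLE_RATE)
            pad = int(pad_s * SAMPLE_RATE)
            t = 0
            while t < len(x):
                yield t / SAMPLE_RATE, AudioClip(x[t : t + size + pad])
                t += size

        ev_a, sec_a = detect_calls_chunked(chunks(20.0))
        ev_b, sec_b = detect_calls_chunked(chunks(35.0))
        assert len(ev_a) == len(ev_b)
        for ct in DEFAULT_SPECS:
            assert sec_a[ct] == pytest.approx(sec_b[ct], rel=0.02)

    def test_wrong_sample_rate_raises_unless_resampling_enabled(self):
        clip = AudioClip(np.zeros(8000 * 2, dtype=np.float32), sample_rate=8000)
        with pytest.raises(ValueError, match="16000"):
            detect_calls(clip)


class TestDetectionRangeRule:
    def test_boundary_convention(self):
        events = pd.DataFrame(
            [
                dict(call_type="chick_beg", start_s=0, duration_s=0.3, position_m=17.0),
                dict(call_type="chick_beg", start_s=1, duration_s=0.3, position_m=16.0),
                dict(call_type="adult_purr", start_s=2, duration_s=1.5, position_m=26.0),
                dict(call_type="adult_purr", start_s=3, duration_s=1.5, position_m=-26.5),
            ]
        )
        out = apply_detection_range(events)
        assert list(out["detected"]) == [False, True, True, False]

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            DetectionRanges(adult_purr=-5.0)

    def test_overlap_fraction_small_under_default_spacing(self, colony):
        from burrowcall.playback_abundance import restrict_to_detection_range

        cfg, plots, nests, _ = colony
        within = restrict_to_detection_range(nests, call_type="adult_chat", plots=plots)
        overlap = (within["audible_plots"] >= 2).mean()
        assert 0.0 < overlap < 0.15


class TestEstimateDetectionRange:
    def test_sharp_cutoff_recovered(self):
        pos = np.arange(-30, 31, 2, dtype=float)
        det = np.abs(pos) <= 16
        r, censored = estimate_detection_range(pos, det)
        assert r == 16.0 and not censored

    def test_asymmetric_sides_average(self):
        pos = np.arange(-40, 41, 2, dtype=float)
        det = ((pos <= 0) & (pos >= -26)) | ((pos >= 0) & (pos <= 30))
        r, _ = estimate_detection_range(pos, det)
        assert r == 28.0

    def test_censored_when_detected_to_test_limit(self):
        pos = np.arange(-20, 21, 2, dtype=float)
        det = np.ones_like(pos, dtype=bool)
        r, censored = estimate_detection_range(pos, det)
        assert r == 20.0 and censored

    def test_no_detections_warns_and_returns_zero(self):
        pos = np.arange(-10, 11, 2, dtype=float)
        with pytest.warns(UserWarning):
            r, _ = estimate_detection_range(pos, np.zeros_like(pos, dtype=bool))
        assert r == 0.0

    def test_sweep_over_rendered_audio_recovers_configured_ranges(self):
        # the audio-path analogue of a field detection-range test, on a
        # coarse grid to stay fast
        ranges = DetectionRanges()
        for ct, step in [("adult_purr", 4), ("chick_beg", 4)]:
            spec = DEFAULT_SPECS[ct]
            pos = np.arange(2.0, 42.0, step)
            det = []
            for i, d in enumerate(pos):
                ev = pd.DataFrame(
                    [
                        dict(
                            call_type=ct,
                            start_s=2.0,
                            duration_s=0.5 * (spec.dur_lo + spec.dur_hi),
                            position_m=float(d),
                        )
                    ]
                )
                clip = render_plot_night(ev, seed=500 + i, duration_s=6.0)
                events, _ = detect_calls(clip)
                det.append((events["call_type"] == ct).any())
            r, _ = estimate_detection_range(pos, det, grid_m=step)
            assert abs(r - ranges.for_type(ct)) <= step


class TestWavRoundTrip:
    def test_write_then_read(self, tmp_path):
        clip = synthesize_call(DEFAULT_SPECS["adult_chat"], seed=8)
        scaled = AudioClip(clip.samples * 0.05)  # unit-RMS bursts peak near 4
        path = tmp_path / "call.wav"
        write_wav(path, scaled)
        back = read_wav(path)
        assert back.sample_rate == SAMPLE_RATE
        assert np.max(np.abs(back.samples - scaled.samples)) < 1e-3
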