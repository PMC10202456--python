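"""Stimulus synthesis: calibration, grids, spectra, determinism."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from icman import stimgen
from icman.waveform import Waveform, active_segments, mix_at_snr, set_level


def band_power_fraction(x, rate, f_lo, f_hi):
    f, p = sp_signal.periodogram(x, rate)
    inband = p[(f >= f_lo) & (f <= f_hi)].sum()
    return inband / p.sum()


class TestLevelCalibration:
    def test_unit_rms_is_94_db(self, rng):
        w = Waveform(rng.standard_normal(4096))
        assert set_level(w, 94.0).rms() == pytest.approx(1.0, abs=1e-9)

    def test_20_db_is_factor_10(self, rng):
        w = Waveform(rng.standard_normal(4096))
        assert set_level(w, 74.0).rms() == pytest.approx(0.1, abs=1e-9)

    def test_rescaling_is_idempotent(self):
        t = np.arange(2048) / 24414.0625
        w = Waveform(0.5 * np.sqrt(2) * np.sin(2 * np.pi * 1000 * t))
        assert set_level(w, 94.0).rms() == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("level", [25.0, 40.0, 70.0, 100.0])
    def test_level_round_trip(self, level, rng):
        w = Waveform(rng.standard_normal(8192))
        assert set_level(w, level).level_db() == pytest.approx(level, abs=0.01)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            set_level(Waveform(np.zeros(100)), 60.0)


class TestToneStream:
    def test_default_grid_has_336_tones(self):
        _, labels = stimgen.make_tone_stream(levels=np.array([60.0]))
        tones = [l for l in labels if l.kind == "tone"]
        assert len(tones) == 21
        freqs = stimgen.tone_freq_grid()
        levels = stimgen.level_grid()
        assert freqs.size * levels.size == 336

    def test_plateau_level_calibrated(self):
        w, labels = stimgen.make_tone_stream(freqs=np.array([1000.0]),
                                             levels=np.array([94.0]))
        lab = [l for l in labels if l.kind == "tone"][0]
        i0 = int(lab.onset_s * w.rate_hz)
        i1 = i0 + int(lab.duration_s * w.rate_hz)
        plateau = w.samples[i0 + 400:i1 - 400]  # past the 10 ms ramps
        assert np.sqrt(np.mean(plateau ** 2)) == pytest.approx(1.0, rel=0.01)

    def test_ramp_starts_at_zero(self):
        w, labels = stimgen.make_tone_stream(freqs=np.array([1000.0]),
                                             levels=np.array([70.0]))
        assert w.samples[0] == pytest.approx(0.0, abs=1e-12)

    def test_labels_tile_stream(self):
        w, labels = stimgen.make_tone_stream(freqs=np.array([500.0, 1000.0]),
                                             levels=np.array([60.0, 70.0]))
        end = 0.0
        for lab in labels:
            assert lab.onset_s == pytest.approx(end, abs=1e-9)
            end = lab.onset_s + lab.duration_s
        assert end == pytest.approx(w.duration_s, abs=1e-6)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_tone_stream(freqs=np.array([13000.0]),
                                     levels=np.array([60.0]))


class TestSamStream:
    def test_freq_sweep_has_24_modulation_frequencies(self):
        _, labels = stimgen.make_sam_stream("freq_sweep", levels=np.array([60.0]))
        fms = {l.mod_freq_hz for l in labels if l.kind == "sam_freq"}
        assert len(fms) == 24
        assert min(fms) == 10.0 and max(fms) == 240.0

    def test_depth_sweep_is_20_log_steps(self):
        _, labels = stimgen.make_sam_stream("depth_sweep", levels=np.array([60.0]))
        depths = sorted({l.mod_depth for l in labels if l.kind == "sam_depth"})
        assert len(depths) == 20
        assert depths[0] == pytest.approx(0.1)
        assert depths[-1] == pytest.approx(1.0)
        ratios = np.diff(np.log(depths))
        assert np.allclose(ratios, ratios[0], rtol=1e-6)

    def test_full_depth_envelope_minima_near_zero(self):
        w, labels = stimgen.make_sam_stream("freq_sweep", levels=np.array([70.0]))
        lab = next(l for l in labels if l.kind == "sam_freq" and l.mod_freq_hz == 30.0)
        i0 = int(lab.onset_s * w.rate_hz)
        seg = w.samples[i0:i0 + int(0.1 * w.rate_hz)]
        env = np.abs(sp_signal.hilbert(seg))
        assert env.min() < 0.05 * env.max()

    @pytest.mark.parametrize("depth", [0.3, 0.6, 1.0])
    def test_measured_modulation_depth(self, depth, rng):
        # regress the squared analytic envelope of a long burst on the
        # modulator basis; the fitted depth must match the request within 5%
        rate = 24414.0625
        n = int(2.0 * rate)
        t = np.arange(n) / rate
        fm = 30.0
        carrier = stimgen.bandpass_noise(n, rate, 500.0, 8000.0, rng)
        x = carrier * (1.0 + depth * np.sin(2 * np.pi * fm * t))
        env2 = np.abs(sp_signal.hilbert(x)) ** 2
        basis = np.column_stack([np.ones(n), np.sin(2 * np.pi * fm * t),
                                 np.cos(2 * np.pi * fm * t),
                                 np.sin(4 * np.pi * fm * t),
                                 np.cos(4 * np.pi * fm * t)])
        beta, *_ = np.linalg.lstsq(basis, env2, rcond=None)
        # (1 + d sin)^2 has mean 1 + d^2/2 and fundamental amplitude 2d,
        # so r = amp/mean = 2d/(1 + d^2/2); invert for d
        r = np.hypot(beta[1], beta[2]) / beta[0]
        d_est = (2.0 - np.sqrt(max(4.0 - 2.0 * r ** 2, 0.0))) / r
        assert d_est == pytest.approx(depth, rel=0.05)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_sam_stream("depth_sweep_bad")


class TestNarrowband:
    def test_cf_grid_is_9_by_9(self):
        grid = stimgen.narrowband_cf_grid()
        assert grid.size == 9
        assert grid[0] == 500.0 and grid[-1] == pytest.approx(8000.0)

    def test_masker_level_matches_target(self):
        tgt, msk = stimgen.make_narrowband_pair(1000.0, 4000.0, 65.0, seed=5)
        assert msk.level_db() == pytest.approx(tgt.level_db(), abs=1e-6)

    def test_target_envelope_period_50_ms(self):
        tgt, _ = stimgen.make_narrowband_pair(2000.0, 2000.0, 70.0, seed=1,
                                              dur_s=1.0)
        env2 = np.abs(sp_signal.hilbert(tgt.samples)) ** 2
        f, p = sp_signal.periodogram(env2 - env2.mean(), tgt.rate_hz)
        assert f[np.argmax(p)] == pytest.approx(20.0, abs=1.5)

    def test_band_power_inside_half_octave(self):
        tgt, msk = stimgen.make_narrowband_pair(2000.0, 1000.0, 70.0, seed=2)
        assert band_power_fraction(tgt.samples, tgt.rate_hz,
                                   2000 * 2 ** -0.3, 2000 * 2 ** 0.3) > 0.95
        assert band_power_fraction(msk.samples, msk.rate_hz,
                                   1000 * 2 ** -0.35, 1000 * 2 ** 0.35) > 0.95


class TestConsonants:
    def test_default_has_22_ids_with_10_instances(self):
        _, labels = stimgen.make_consonant_tokens(seed=0)
        cons = [l for l in labels if l.kind == "consonant"]
        ids = {}
        for l in cons:
            ids.setdefault(l.consonant_id, 0)
            ids[l.consonant_id] += 1
        assert sorted(ids) == list(range(1, 23))
        assert all(v >= 10 for v in ids.values())

    def test_fricative_power_above_4khz(self):
        rng = np.random.default_rng(0)
        tok = stimgen._consonant_token(18, 5, 24414.0625, rng)
        assert band_power_fraction(tok, 24414.0625, 4000.0, 12207.0) > 0.7

    def test_vowel_like_power_below_2khz(self):
        rng = np.random.default_rng(0)
        tok = stimgen._consonant_token(3, 5, 24414.0625, rng)
        assert band_power_fraction(tok, 24414.0625, 50.0, 2000.0) > 0.7

    def test_deterministic_given_seed(self):
        w1, l1 = stimgen.make_consonant_tokens(seed=7)
        w2, l2 = stimgen.make_consonant_tokens(seed=7)
        assert np.array_equal(w1.samples, w2.samples)
        assert [x.consonant_id for x in l1] == [x.consonant_id for x in l2]

    def test_too_few_consonants_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_consonant_tokens(n_consonants=2)


class TestBabble:
    def test_low_frequency_dominated(self):
        w = stimgen.make_babble(duration_s=1.0, seed=3)
        below = band_power_fraction(w.samples, w.rate_hz, 20.0, 1000.0)
        above = band_power_fraction(w.samples, w.rate_hz, 4000.0, 12000.0)
        assert below > above

    def test_rms_grows_like_sqrt_k(self):
        r4 = stimgen.make_babble(n_talkers=4, duration_s=1.0, seed=9).rms()
        r16 = stimgen.make_babble(n_talkers=16, duration_s=1.0, seed=9).rms()
        assert r16 / r4 == pytest.approx(2.0, rel=0.35)

    def test_deterministic(self):
        a = stimgen.make_babble(duration_s=0.5, seed=2)
        b = stimgen.make_babble(duration_s=0.5, seed=2)
        assert np.array_equal(a.samples, b.samples)


class TestMixAtSnr:
    @pytest.mark.parametrize("snr", [0.0, 3.0, 20.0])
    def test_snr_round_trip(self, snr, rng):
        speech, _ = stimgen.make_consonant_tokens(n_consonants=4, n_talkers=3,
                                                  seed=1)
        noise = stimgen.make_babble(duration_s=speech.duration_s + 0.1, seed=2)
        mixed = mix_at_snr(speech, noise, snr_db=snr)
        mask = active_segments(speech)
        s_rms = np.sqrt(np.mean(speech.samples[mask] ** 2))
        n_only = mixed.samples - speech.samples
        n_rms = np.sqrt(np.mean(n_only[: speech.n_samples] ** 2))
        assert 20 * np.log10(s_rms / n_rms) == pytest.approx(snr, abs=0.1)

    def test_silent_noise_rejected(self):
        speech = Waveform(np.sin(np.arange(4096) * 0.1))
        with pytest.raises(ValueError):
            mix_at_snr(speech, Waveform(np.zeros(8192)), 3.0)
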