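"""Shepard-tone construction and the two stimulus paradigms."""

import numpy as np
import pytest

from shepadapt.circular import circular_distance, circular_step
from shepadapt.stimuli import (PairConfig, ShepardTone, TuningConfig,
                               component_frequencies, generate_biased_pair_set,
                               generate_biased_tuning_set, synthesize_waveform,
                               to_spectrogram)


class TestComponentFrequencies:
    def test_anchor_440(self):
        freqs = component_frequencies(0.0, (400.0, 900.0))
        assert 440.0 in freqs.tolist()

    def test_octave_circularity(self):
        a = component_frequencies(12.0, (20.0, 20000.0))
        b = component_frequencies(0.0, (20.0, 20000.0))
        np.testing.assert_allclose(a, b)

    def test_tritone_single_component(self):
        freqs = component_frequencies(6.0, (600.0, 700.0))
        np.testing.assert_allclose(freqs, [440.0 * 2 ** 0.5], rtol=1e-9)
        assert freqs[0] == pytest.approx(622.25, abs=0.01)

    def test_components_octave_spaced_ascending(self):
        freqs = component_frequencies(4.3, (30.0, 16000.0))
        ratios = freqs[1:] / freqs[:-1]
        np.testing.assert_allclose(ratios, 2.0, rtol=1e-12)

    def test_empty_band_errors(self):
        with pytest.raises(ValueError):
            component_frequencies(0.0, (900.0, 400.0))


class TestWaveform:
    def test_seeded_determinism(self):
        tone = ShepardTone(3.0, phase_seed=42)
        w1 = synthesize_waveform(tone, 44100.0)
        w2 = synthesize_waveform(tone, 44100.0)
        np.testing.assert_array_equal(w1, w2)

    def test_spectral_peaks_at_components(self):
        tone = ShepardTone(2.0, duration=1.0, ramp=5.0, phase_seed=1)
        fs = 44100.0
        w = synthesize_waveform(tone, fs)
        spec = np.abs(np.fft.rfft(w * np.hanning(w.size)))
        freqs = np.fft.rfftfreq(w.size, 1 / fs)
        expected = component_frequencies(2.0, (30.0, 16000.0))
        # every strong spectral line lies within the mainlobe of a component
        strong = freqs[spec > 0.05 * spec.max()]
        for f in strong:
            assert np.min(np.abs(expected - f)) < 3.0

    def test_onset_ramp_is_half_cosine(self):
        fs = 80000.0
        tone = ShepardTone(0.0, duration=0.1, ramp=5.0, phase_seed=3)
        w = synthesize_waveform(tone, fs)
        unramped = ShepardTone(0.0, duration=0.1, ramp=0.0, phase_seed=3)
        wu = synthesize_waveform(unramped, fs)
        n = int(round(0.005 * fs))
        gate = 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / n))
        np.testing.assert_allclose(w[:n], wu[:n] * gate, atol=1e-6)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            synthesize_waveform(ShepardTone(0.0), audio_rate=8000.0)


class TestBiasedPairSet:
    def test_design_counts(self, pair_sequences):
        # 32 distinct bias sequences containing 240 distinct bias tones
        assert len({s.bias_id for s in pair_sequences}) == 32
        distinct_tones = {(s.bias_id, e.onset) for s in pair_sequences
                          for e in s.tones("bias")}
        assert len(distinct_tones) == 240
        # one ToneSequence per (bias sequence, gap)
        assert len(pair_sequences) == 32 * 3

    def test_factorial_and_seed_reproducibility(self):
        cfg = PairConfig()
        a = generate_biased_pair_set(cfg, seed=5)
        b = generate_biased_pair_set(cfg, seed=5)
        assert [s.seq_id for s in a] == [s.seq_id for s in b]
        pcs_a = [e.tone.pitch_class for s in a for e in s.events]
        pcs_b = [e.tone.pitch_class for s in b for e in s.events]
        np.testing.assert_array_equal(pcs_a, pcs_b)

    def test_bias_range_up_and_down(self, pair_sequences):
        for seq in pair_sequences:
            base = seq.base_pc
            sgn = 1.0 if seq.bias_meta.direction == "up" else -1.0
            for ev in seq.tones("bias"):
                offset = sgn * circular_step(base, ev.tone.pitch_class)
                # strictly within (test1, test1 + 6) on the bias side
                assert 0.0 < offset < 6.0
                assert 0.5 - 1e-9 <= offset <= 5.5 + 1e-9

    def test_pair_geometry_and_order(self, pair_sequences):
        for seq in pair_sequences:
            t1 = seq.tones("test1")[0]
            t2 = seq.tones("test2")[0]
            last_bias = max(e.onset for e in seq.tones("bias"))
            assert t1.onset > last_bias
            assert t2.onset > t1.onset
            assert circular_distance(t1.tone.pitch_class, t2.tone.pitch_class) == \
                pytest.approx(6.0)

    def test_wide_bias_rejected(self):
        with pytest.raises(ValueError):
            generate_biased_pair_set(PairConfig(bias_range=12.0), seed=0)


class TestBiasedTuningSet:
    @pytest.fixture(scope="class")
    def tuning_seqs(self):
        return generate_biased_tuning_set(TuningConfig(), seed=3)

    def test_probe_grid_half_semitone(self, tuning_seqs):
        probes = {e.tone.pitch_class for s in tuning_seqs for e in s.tones("probe")}
        for pc in probes:
            assert (pc * 2) == pytest.approx(round(pc * 2), abs=1e-9)

    def test_region_set(self, tuning_seqs):
        regions = {s.region for s in tuning_seqs}
        assert regions == {(0.0, 5.0), (3.0, 8.0), (6.0, 11.0), (9.0, 14.0)}
        for s in tuning_seqs:
            lo, hi = s.region
            for e in s.tones("bias") + s.tones("lead_in"):
                d = (e.tone.pitch_class - lo) % 12.0
                assert d <= (hi - lo) + 1e-9

    def test_probe_fraction_and_length(self, tuning_seqs):
        for s in tuning_seqs:
            assert len(s.events) == 154
            n_lead = len(s.tones("lead_in"))
            n_probe = len(s.tones("probe"))
            assert n_lead == 15
            frac = n_probe / (len(s.events) - n_lead)
            assert abs(frac - 1 / 6) < 1 / (len(s.events) - n_lead) + 1e-9

    def test_probe_coverage_balanced(self, tuning_seqs):
        from collections import Counter
        for region in {(0.0, 5.0), (3.0, 8.0)}:
            seqs = [s for s in tuning_seqs if s.region == region]
            counts = Counter(round(e.tone.pitch_class * 2) for s in seqs
                             for e in s.tones("probe"))
            assert len(counts) == 24
            assert max(counts.values()) - min(counts.values()) <= 1


class TestSpectrogram:
    def test_tone_occupies_two_frames(self):
        seqs = generate_biased_pair_set(PairConfig(gaps=(0.5,)), seed=0)
        spec = to_spectrogram(seqs[0], sample_rate=20.0, n_bins=24)
        # every tone is 0.1 s = exactly 2 frames at 20 Hz
        n_tones = len(seqs[0].events)
        assert spec.frames.sum() == pytest.approx(2 * n_tones)
        assert ((spec.frames == 0) | (spec.frames == 1)).all()

    def test_pause_frames_silent(self):
        seqs = generate_biased_pair_set(PairConfig(gaps=(0.5,)), seed=0)
        seq = seqs[0]
        spec = to_spectrogram(seq, 20.0, 24)
        # the frame right before test1 lies in the 0.5 s gap
        t1 = seq.tones("test1")[0].onset
        gap_frame = int(t1 * 20) - 2
        assert spec.frames[gap_frame].sum() == 0

    def test_circular_bin_wrap(self):
        from shepadapt.stimuli import pitch_bin
        assert pitch_bin(11.9, 24) == 0
        assert pitch_bin(11.7, 24) == 23

    def test_energy_conservation(self, pair_sequences):
        for seq in pair_sequences[:4]:
            spec = to_spectrogram(seq, 20.0, 24)
            assert spec.frames.sum() == pytest.approx(2 * len(seq.events))


class TestMegProbeVariant:
    def test_timing_and_probe_geometry(self):
        from shepadapt.stimuli import generate_meg_probe_set
        seqs = generate_meg_probe_set(PairConfig(), seed=2)
        assert len(seqs) == 32 * 3  # 32 bias sequences x 3 pauses
        seq = seqs[0]
        bias = seq.tones("bias")
        # 4 Hz presentation with 125 ms tones
        assert bias[1].onset - bias[0].onset == pytest.approx(0.25)
        assert bias[0].tone.duration == pytest.approx(0.125)
        probes = seq.tones("probe")
        assert len(probes) == 8  # 2 s train at 250 ms SOA
        assert probes[0].tone.duration == pytest.approx(0.03)
        # probe pitch 3 st on the bias side of the first pair tone
        sgn = 1.0 if seq.bias_meta.direction == "up" else -1.0
        assert circular_step(seq.base_pc, probes[0].tone.pitch_class) == \
            pytest.approx(sgn * 3.0)
        # pair follows the probe train
        assert seq.tones("test1")[0].onset > probes[-1].onset
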