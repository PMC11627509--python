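"""PSTH windows, response types, recovery fits, biased tuning, halfwidth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shepadapt import adaptation as ad
from shepadapt.cohort import NoiseConfig, simulate_experiment
from shepadapt.dynamic_model import ModelConfig, make_population, preferred_tone_response
from shepadapt.pipeline import f_r_for_recovery
from shepadapt.stimuli import TuningConfig, generate_biased_tuning_set
from shepadapt.tuning import VonMisesTuning


class TestPSTHWindows:
    def test_windows_tile_the_soa(self):
        # three 50 ms windows cover the 150 ms onset asynchrony exactly
        assert len(ad.WINDOW_NAMES) * 0.05 == pytest.approx(0.15)

    def test_constant_cell_equal_windows(self, cohort_response):
        """A cell's spontaneous-only activity has equal expected rate in
        every window; the trial-averaged PSTH table is well formed."""
        tbl = ad.psth_windows(cohort_response.subset(np.arange(4)), roles=("bias",))
        assert set(tbl["window"]) == {"onset", "sustained", "offset"}
        assert (tbl["rate"] >= 0).all()
        # every (sequence, position) yields all three windows
        counts = tbl.groupby(["seq_id", "position"])["window"].nunique()
        assert (counts == 3).all()

    def test_position_psth_onset_adapts(self, cohort_response):
        psth = ad.position_psth(cohort_response, roles=("bias",), window="onset",
                                max_position=10).mean(axis=0)
        assert psth[1] > psth[-1]


class TestResponseType:
    def test_known_decay_recovered(self):
        """Exponential series with tau = 3.9 positions and 13% plateau
        is classified adapting with tau recovered closely."""
        k = np.arange(1, 11, dtype=float)
        r = 10.0 * (0.87 + 0.13 * np.exp(-(k - 1) / 3.9))
        res = ad.classify_response_type(r)
        assert res.label == "adapting"
        assert res.tau_stimuli == pytest.approx(3.9, rel=0.1)
        assert (res.initial_rate - res.asymptote_rate) / res.initial_rate == \
            pytest.approx(0.13, abs=0.02)

    def test_cohort_decay_with_noise(self):
        """A 662-series cohort of noisy exponential decays recovers the
        population time constant within 15% and plateau within 3 points."""
        rng = np.random.default_rng(8)
        k = np.arange(1, 11, dtype=float)
        clean = 0.87 + 0.13 * np.exp(-(k - 1) / 3.9)
        series = clean[None, :] * 20.0 + rng.normal(0, 0.8, size=(662, 10))
        res = ad.classify_response_type(series.mean(axis=0))
        assert res.tau_stimuli == pytest.approx(3.9, rel=0.15)
        plateau = (res.initial_rate - res.asymptote_rate) / res.initial_rate
        assert plateau == pytest.approx(0.13, abs=0.03)

    def test_increasing_ramp_is_facilitating(self):
        res = ad.classify_response_type(np.linspace(5, 9, 8))
        assert res.label == "facilitating"

    def test_constant_series_flat(self):
        res = ad.classify_response_type(np.full(8, 4.0))
        assert res.label == "flat"

    def test_needs_four_positions(self):
        with pytest.raises(ValueError):
            ad.classify_response_type(np.array([3.0, 2.0, 1.0]))


class TestRecoveryFit:
    def test_exact_exponential_recovery(self):
        t = np.linspace(0.3, 3.0, 50)
        r = 2.0 - 0.4 * np.exp(-t / 1.2)
        tau, diag = ad.recovery_fit(t, r)
        assert not diag["degenerate"]
        assert tau == pytest.approx(1.2, rel=1e-4)

    def test_model_recovery_matches_configured_f_r(self, cohort_response):
        """Spontaneous rates after the bias recover with the time
        constant implied by F_R (1.2 s) within 15%."""
        times, rates = ad.spontaneous_recovery_trace(cohort_response)
        tau, diag = ad.recovery_fit(times, rates)
        assert not diag["degenerate"]
        assert tau == pytest.approx(1.2, rel=0.15)

    def test_no_adaptation_flagged_degenerate(self, pair_sequences):
        pop = make_population(ModelConfig(n_cortical=60, f_a=0.0))
        pref = preferred_tone_response(pop)
        pop.rate_gain = 20.0 / np.where(pref > 0, pref, 1.0)
        resp = simulate_experiment(pair_sequences[:16], pop,
                                   NoiseConfig(repetitions=1, mode="rate"), seed=2)
        times, rates = ad.spontaneous_recovery_trace(resp)
        tau, diag = ad.recovery_fit(times, rates)
        assert diag["degenerate"]

    def test_doubling_f_r_roughly_halves_tau(self):
        """Monotone sweep: the closed-form relation between F_R and the
        recovery time constant."""
        taus = []
        for tau_target in (2.4, 1.2, 0.6):
            fr = f_r_for_recovery(tau_target)
            taus.append(-1.0 / (20.0 * np.log(1.0 - fr)))
        assert taus[0] == pytest.approx(2 * taus[1], rel=1e-9)
        assert taus[1] == pytest.approx(2 * taus[2], rel=1e-9)


class TestTuningHalfwidth:
    def test_von_mises_analytic_width(self):
        """Grid estimate matches the closed-form half-height crossing."""
        for sigma in (0.6, 1.0, 1.8):
            vm = VonMisesTuning(best_pc=4.0, width=sigma, normalization="peak_one")
            grid = np.linspace(0, 12, 240, endpoint=False)
            hw, flag = ad.tuning_halfwidth(vm(grid), grid)
            assert not flag
            assert hw == pytest.approx(vm.halfwidth_analytic(), abs=0.06)

    def test_flat_curve_degenerate(self):
        hw, flag = ad.tuning_halfwidth(np.full(24, 3.3))
        assert hw == 12.0
        assert flag

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(12)
        curve = rng.random(24) + 0.5
        hw1, f1 = ad.tuning_halfwidth(curve)
        hw2, f2 = ad.tuning_halfwidth(a * curve + b)
        assert hw1 == pytest.approx(hw2, abs=1e-9)
        assert f1 == f2

    def test_weak_modulation_gives_wide_halfwidth(self):
        """The estimator is conservative: a barely modulated curve gets
        a large halfwidth."""
        grid = np.linspace(0, 12, 240, endpoint=False)
        sharp = VonMisesTuning(2.0, 0.8, normalization="peak_one")(grid)
        weak = 10.0 + 0.1 * sharp
        hw_sharp, _ = ad.tuning_halfwidth(sharp, grid)
        hw_weak, _ = ad.tuning_halfwidth(weak, grid)
        assert hw_weak == pytest.approx(hw_sharp, abs=1e-9)  # affine only
        shallow = 10.0 + 0.1 * np.cos(2 * np.pi * grid / 12.0)
        hw_shallow, _ = ad.tuning_halfwidth(shallow, grid)
        assert hw_shallow > 5.0


class TestBiasedTuning:
    @pytest.fixture(scope="class")
    def tuning_response(self, small_cohort):
        pop, meta = small_cohort
        cfg = TuningConfig(sequence_length=80, sequences_per_region=3)
        seqs = generate_biased_tuning_set(cfg, seed=9)
        resp = simulate_experiment(seqs, pop, NoiseConfig(tail=0.5), seed=19,
                                   neuron_meta=meta)
        return cfg, resp

    def test_reduction_local_to_bias(self, tuning_response):
        """The response reduction is concentrated inside the bias
        region (mean inside at least twice the outside mean)."""
        cfg, resp = tuning_response
        comp = ad.biased_tuning(resp, cfg.regions)
        inside, outside = comp.mean_reduction()
        assert inside > 0
        assert inside > 2 * abs(outside)

    def test_region_profiles_agree_after_recentering(self, tuning_response):
        """Re-centered difference profiles of the four regions agree
        (rotation invariance of the model), within a loose band."""
        cfg, resp = tuning_response
        comp = ad.biased_tuning(resp, cfg.regions)
        prof = np.nanmean(comp.difference_centered, axis=1)  # (region, 24)
        grand = np.nanmean(prof, axis=0)
        spread = np.nanmean(np.abs(prof - grand[None, :]))
        assert spread < max(0.5 * np.nanmax(np.abs(grand)), 1.0)

    def test_no_adaptation_flat_difference(self, small_cohort):
        pop, meta = small_cohort
        import dataclasses
        from shepadapt.cohort import CohortConfig, emulate_recorded_cohort
        pop0, meta0 = emulate_recorded_cohort(CohortConfig(n=120),
                                              ModelConfig(f_a=0.0), seed=4)
        cfg = TuningConfig(sequence_length=80, sequences_per_region=2)
        seqs = generate_biased_tuning_set(cfg, seed=9)
        resp = simulate_experiment(seqs, pop0, NoiseConfig(tail=0.3), seed=29,
                                   neuron_meta=meta0)
        comp = ad.biased_tuning(resp, cfg.regions)
        inside, outside = comp.mean_reduction()
        # no systematic reduction anywhere without adaptation
        assert abs(inside) < 1.0 and abs(outside) < 1.0


class TestAdaptingFraction:
    def test_cohort_adapting_fraction_recovered(self):
        """With adequate stimulus sampling, at least the configured 91%
        of cells are classified adapting at 10 Poisson repetitions."""
        from shepadapt import study
        m = study.response_type_experiment(seed=5)
        assert m["fraction_adapting"] >= 0.91
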