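"""Dynamic SSTRF + synaptic-depression model."""

import numpy as np
import pytest
from dataclasses import replace

from shepadapt.circular import circular_step, wrap_pc
from shepadapt.dynamic_model import (AdaptationState, ModelConfig,
                                     build_directional_sstrf, make_population,
                                     preferred_tone_response, simulate_rates,
                                     step_dynamic_model)
from shepadapt.stimuli import PairConfig, generate_biased_pair_set, to_spectrogram


def _tone_spec(pc, n_frames=40, n_bins=24, period=3, duration=2):
    """Spectrogram of a repeated identical tone (period in frames)."""
    frames = np.zeros((n_frames, n_bins))
    b = int(round(pc * n_bins / 12)) % n_bins
    for start in range(0, n_frames - duration, period):
        frames[start:start + duration, b] = 1.0
    from shepadapt.stimuli import PitchClassSpectrogram
    return PitchClassSpectrogram(frames=frames, sample_rate=20.0, n_bins=n_bins)


class TestSSTRFConstruction:
    def test_nondirectional_late_lags_zero(self):
        cfg = ModelConfig()
        w = build_directional_sstrf(4.0, "none", cfg)
        assert np.all(w[2:] == 0)
        assert w[0].max() == pytest.approx(1.0)
        np.testing.assert_allclose(w[1], w[0])

    @pytest.mark.parametrize("direction, sign", [("down", +1), ("up", -1)])
    def test_late_lobe_placement(self, direction, sign):
        cfg = ModelConfig()
        w = build_directional_sstrf(4.0, direction, cfg)
        mid_pcs = 12.0 * np.arange(cfg.n_midlevel) / cfg.n_midlevel
        # late lobe lives at lags 3-4 (150-250 ms at 20 Hz)
        assert np.all(w[2] == 0)
        late_center = mid_pcs[np.argmax(w[3])]
        assert circular_step(4.0, late_center) == pytest.approx(
            sign * cfg.directional_offset, abs=0.13)

    def test_late_lobe_peak_ratio(self):
        w = build_directional_sstrf(0.0, "up", ModelConfig())
        assert w[3].max() / w[0].max() == pytest.approx(0.25, abs=1e-9)


class TestMakePopulation:
    def test_default_nondirectional_layout(self):
        pop = make_population(ModelConfig(n_cortical=100))
        assert pop.n_cells == 100
        np.testing.assert_allclose(np.diff(np.sort(pop.best_pcs)), 0.12, atol=1e-9)
        assert set(pop.directions) == {"none"}

    def test_directional_thirds(self):
        pop = make_population(ModelConfig(n_cortical=500, directional_fraction=2 / 3))
        counts = {d: int(np.sum(pop.directions == d)) for d in ("up", "down", "none")}
        for c in counts.values():
            assert abs(c - 500 / 3) <= 1.5

    def test_labels_match_constructed_lobes(self):
        cfg = ModelConfig(n_cortical=60, directional_fraction=2 / 3)
        pop = make_population(cfg)
        mid_pcs = pop.midlevel.best_pcs
        for i in range(pop.n_cells):
            if pop.directions[i] == "none":
                assert np.all(pop.sstrfs[i, 3] == 0)
                continue
            late_center = mid_pcs[np.argmax(pop.sstrfs[i, 3])]
            offset = circular_step(pop.best_pcs[i], late_center)
            expected = cfg.directional_offset if pop.directions[i] == "down" \
                else -cfg.directional_offset
            assert offset == pytest.approx(expected, abs=0.13)


class TestDynamics:
    def test_no_adaptation_equals_linear_filter(self):
        cfg = ModelConfig(f_a=0.0)
        pop = make_population(cfg)
        spec = _tone_spec(3.0)
        rates, state = simulate_rates(pop, spec)
        assert np.all(state.A == 0)
        # direct linear evaluation at an arbitrary frame
        T = pop.midlevel.activity_trace(spec.frames)
        t = 7
        lin = np.einsum("nlj,lj->n",
                        pop.sstrfs,
                        np.stack([T[t - lag] for lag in range(cfg.n_lags)])) / cfg.n_midlevel
        np.testing.assert_allclose(rates[t], np.clip(lin, 0, None), rtol=1e-12)

    def test_recovery_is_exact_geometric_decay(self):
        cfg = ModelConfig()
        pop = make_population(cfg)
        A0 = np.full((pop.n_cells, cfg.n_midlevel), 0.2)
        state = AdaptationState(A=A0.copy())
        zeros = np.zeros((cfg.n_lags, cfg.n_midlevel))
        for k in range(1, 8):
            _, state = step_dynamic_model(state, pop, zeros)
            np.testing.assert_allclose(state.A, A0 * (1 - cfg.f_r) ** k, rtol=1e-12)

    def test_constant_drive_fixed_point(self):
        """Iterated depression converges to the algebraic fixed point
        A* = (A* + F_A d (1 - A*)) (1 - F_R)."""
        cfg = ModelConfig(n_cortical=4, n_midlevel=8, a_max=1.0)
        pop = make_population(cfg)
        pop.sstrfs[:] = 0.0
        pop.sstrfs[:, 0, :] = 1.0  # uniform weights -> uniform drive
        T = np.zeros((cfg.n_lags, cfg.n_midlevel))
        T[0, :] = 0.5 / cfg.n_bins  # peak-normalized drive d = 0.5
        state = AdaptationState.zeros(pop)
        for _ in range(10000):
            _, state = step_dynamic_model(state, pop, T)
        d = 0.5
        # the update is affine in A: A* = (1-Fr) Fa d / (1 - (1-Fr)(1-Fa d))
        fr, fa = cfg.f_r, cfg.f_a
        a_star = (1 - fr) * fa * d / (1 - (1 - fr) * (1 - fa * d))
        np.testing.assert_allclose(state.A, a_star, rtol=1e-6)

    def test_printed_update_cannot_grow_from_zero(self):
        cfg = ModelConfig(printed_update=True)
        pop = make_population(cfg)
        spec = _tone_spec(3.0)
        _, state = simulate_rates(pop, spec)
        assert np.all(state.A == 0)

    def test_repeated_tone_onset_decreases_to_plateau(self):
        cfg = ModelConfig()
        pop = make_population(cfg)
        spec = _tone_spec(6.0, n_frames=61, period=3)
        rates, _ = simulate_rates(pop, spec)
        onsets = rates[0:60:3].mean(axis=1)
        diffs = np.diff(onsets)
        assert np.all(diffs <= 1e-12)
        # approaches a plateau: late decrements much smaller than early
        assert abs(diffs[-1]) < 0.05 * abs(diffs[0]) + 1e-15

    def test_depression_capped_at_a_max(self):
        cfg = ModelConfig(f_a=1.0, a_max=0.3)
        pop = make_population(cfg)
        spec = _tone_spec(0.0, n_frames=100, period=3)
        _, state = simulate_rates(pop, spec)
        assert state.A.max() <= 0.3 + 1e-12


class TestRotationInvariance:
    def test_rotating_stimulus_and_population_rotates_rates(self):
        """The model has no preferred location on the pitch circle:
        rotating stimuli and best pitch classes by 3 st permutes the
        population response accordingly."""
        cfg = ModelConfig(n_cortical=48, n_midlevel=48)
        directions = np.tile(np.array(["up", "down", "none"], dtype=object), 16)
        pop = make_population(cfg, directions=directions)
        spec = _tone_spec(2.0, n_frames=30)
        rates, _ = simulate_rates(pop, spec)
        spec_rot = _tone_spec(5.0, n_frames=30)
        rates_rot, _ = simulate_rates(pop, spec_rot)
        # cells are equally spaced every 0.25 st, so +3 st = 12 indices;
        # the direction pattern has period 3 cells and 12 % 3 == 0, so
        # the rolled population is identical cell-for-cell
        np.testing.assert_allclose(rates_rot, np.roll(rates, 12, axis=1), atol=1e-10)
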