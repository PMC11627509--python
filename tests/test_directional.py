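"""SSTRF estimation, directionality index, directional decoding, maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shepadapt.circular import circular_distance, circular_step
from shepadapt.cohort import NoiseConfig, simulate_experiment, tone_response_matrix
from shepadapt.dynamic_model import (ModelConfig, build_directional_sstrf,
                                     make_population, preferred_tone_response)
from shepadapt import directional as dr


@pytest.fixture(scope="module")
def estimated(symmetric_response):
    return dr.estimate_sstrf(symmetric_response)


@pytest.fixture(scope="module")
def di_table(estimated):
    return dr.directionality_table(estimated)


class TestDirectionalityIndex:
    def test_symmetric_filter_gives_zero(self):
        cfg = ModelConfig()
        w = build_directional_sstrf(6.0, "none", cfg)
        # add a symmetric late component around the BF
        mid_pcs = 12.0 * np.arange(cfg.n_midlevel) / cfg.n_midlevel
        sym = np.exp(-circular_distance(mid_pcs, 6.0) ** 2)
        w[3] = w[4] = sym
        res = dr.directionality_index(w, mid_pcs)
        assert res.DI == pytest.approx(0.0, abs=1e-9)

    def test_constructed_cells_have_correct_sign_and_mirror(self):
        cfg = ModelConfig()
        mid_pcs = 12.0 * np.arange(cfg.n_midlevel) / cfg.n_midlevel
        up = dr.directionality_index(build_directional_sstrf(6.0, "up", cfg), mid_pcs)
        dn = dr.directionality_index(build_directional_sstrf(6.0, "down", cfg), mid_pcs)
        assert up.DI > 0
        assert dn.DI < 0
        assert abs(up.DI) == pytest.approx(abs(dn.DI), abs=1e-9)

    def test_needs_two_lags(self):
        with pytest.raises(ValueError):
            dr.directionality_index(np.ones((1, 24)), 0.5 * np.arange(24))


class TestSSTRFEstimation:
    def test_lag0_peak_matches_tuning(self, symmetric_population, estimated):
        pop = symmetric_population
        t1 = estimated.weights[:, :2].mean(axis=1)
        err = []
        for i in range(0, pop.n_cells, 7):
            bf_est = estimated.pitch_values[np.argmax(t1[i])]
            err.append(circular_distance(bf_est, pop.best_pcs[i]))
        assert np.median(err) <= 0.5

    def test_late_lobe_recovered_within_1st(self, symmetric_population, estimated):
        pop = symmetric_population
        cfg = pop.cfg
        errs = []
        for i in range(pop.n_cells):
            if pop.directions[i] == "none":
                continue
            sgn = 1.0 if pop.directions[i] == "down" else -1.0
            true_center = np.mod(pop.best_pcs[i] + sgn * cfg.directional_offset, 12.0)
            late = estimated.weights[i, 3:5].mean(axis=0)
            est_center = estimated.pitch_values[np.argmax(late)]
            errs.append(circular_distance(est_center, true_center))
        assert np.median(errs) <= 1.0

    def test_di_sign_recovery_rate(self, symmetric_population, di_table):
        """Estimated DI recovers the constructed direction class sign
        for at least 95% of directional cells at 10 Poisson reps."""
        pop = symmetric_population
        true = np.where(pop.directions == "up", 1.0,
                        np.where(pop.directions == "down", -1.0, 0.0))
        m = true != 0
        agree = np.sign(di_table["DI"].to_numpy())[m] == true[m]
        assert agree.mean() >= 0.95

    def test_white_noise_response_recovers_null(self, pair_sequences):
        """A response independent of the stimulus yields SSTRF weights
        statistically indistinguishable from zero."""
        pop = make_population(ModelConfig(n_cortical=4))
        pop.sstrfs[:] = 0.0  # no stimulus drive at all
        resp = simulate_experiment(pair_sequences[:48], pop,
                                   NoiseConfig(baseline_hz=20.0, tail=0.3), seed=3)
        est = dr.estimate_sstrf(resp)
        w = est.weights
        assert np.abs(w).max() < 3.0 * np.abs(w).std() + 1e-9 or \
            np.abs(w.mean()) < 3 * w.std() / np.sqrt(w.size)


class TestDirectionalDecode:
    def test_uniform_up_population_positive(self):
        d = dr.directional_decode(np.ones(10), np.ones(10),
                                  np.linspace(0, 12, 10, endpoint=False), 3.0)
        assert d > 0

    def test_mirror_antisymmetry(self):
        """Reflecting the pitch circle flips the decoded sign exactly."""
        rng = np.random.default_rng(0)
        com = rng.uniform(0, 12, 40)
        dis = rng.normal(0, 1, 40)
        f = rng.uniform(0, 5, 40)
        d = dr.directional_decode(f, dis, com, 4.0)
        d_ref = dr.directional_decode(f, -dis, np.mod(-com, 12.0), np.mod(-4.0, 12.0))
        assert d_ref == pytest.approx(-d, rel=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            dr.directional_decode(np.array([]), np.array([]), np.array([]), 0.0)

    def test_expected_percept_labels(self):
        assert dr.expected_percept_sign("test1", "up") == -1
        assert dr.expected_percept_sign("test2", "up") == +1
        assert dr.expected_percept_sign("test1", "down") == +1
        assert dr.expected_percept_sign("test2", "down") == -1
        with pytest.raises(ValueError):
            dr.expected_percept_sign("bias", "up")

    @pytest.mark.parametrize("kernel_width", [1.0, 1.5, 2.5])
    def test_balanced_unadapted_population_near_zero(self, kernel_width):
        """With balanced up/down cells all equally active there is no
        percept bias, for any reasonable kernel width."""
        com = np.linspace(0, 12, 60, endpoint=False)
        dis = np.tile([1.0, -1.0], 30)
        d = dr.directional_decode(np.ones(60), dis, com, 3.7, kernel_width)
        assert abs(d) < 1e-9


class TestDifferentialMap:
    def test_map_structure_and_counts(self, symmetric_response, di_table):
        ev, mat = tone_response_matrix(symmetric_response, roles=("test1", "test2"))
        samples = dr.differential_samples(ev, mat, di_table["DI"].to_numpy(),
                                          di_table["com_pc"].to_numpy())
        dmap = dr.differential_response_map(samples)
        assert dmap.grid.shape == (7, 12)
        assert dmap.counts.sum() == len(samples)
        # unpopulated bins are nan-flagged, not zero-filled
        assert np.isnan(dmap.grid[dmap.counts == 0]).all()

    def test_recent_bias_exclusion_rule(self, symmetric_response, di_table):
        ev, mat = tone_response_matrix(symmetric_response, roles=("test1", "test2"))
        s_all = dr.differential_samples(ev, mat, di_table["DI"].to_numpy(),
                                        di_table["com_pc"].to_numpy(),
                                        exclude_recent_bias_s=None)
        s_exc = dr.differential_samples(ev, mat, di_table["DI"].to_numpy(),
                                        di_table["com_pc"].to_numpy())
        assert len(s_exc) < len(s_all)

    def test_near_tone_sign_pattern(self, symmetric_response, di_table):
        """Near the tones, ascending-preferring cells respond less after
        a bias above than below, descending-preferring cells more."""
        ev, mat = tone_response_matrix(symmetric_response, roles=("test1", "test2"))
        samples = dr.differential_samples(ev, mat, di_table["DI"].to_numpy(),
                                          di_table["com_pc"].to_numpy())
        near = samples[np.abs(samples["rel_pc"]) <= 1.5]
        per = near.groupby("cell").agg(DI=("DI", "mean"), d=("diff", "mean"))
        assert per.loc[per["DI"] > 0, "d"].mean() < 0
        assert per.loc[per["DI"] < 0, "d"].mean() > 0

    def test_shuffled_labels_give_uniform_p(self, symmetric_response, di_table):
        """Permuting DI across cells destroys the dependence: the
        near-tone p-values follow the uniform null (KS test)."""
        ev, mat = tone_response_matrix(symmetric_response, roles=("test1", "test2"))
        dis = di_table["DI"].to_numpy()
        samples = dr.differential_samples(ev, mat, dis, di_table["com_pc"].to_numpy())
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(len(dis))
            shuffled = samples.copy()
            shuffled["DI"] = dis[perm][shuffled["cell"].to_numpy()]
            pvals.append(dr.near_tone_test(shuffled))
        pvals = np.asarray(pvals)
        assert np.isfinite(pvals).all()
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
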