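"""End-to-end orchestration: stimuli -> simulation -> analyses -> report.

The stages mirror the study design: generate the two stimulus
paradigms, emulate a recorded cohort with the dynamic adaptation model,
select units, decode represented pitch (PCA circle and population
vector), run the directionality analyses, and fit the adaptation time
courses.  ``calibrate`` tunes the model's adaptation gain/recovery so
the simulated population reproduces target build-up and recovery
statistics; those targets are the study's calibration anchors
(build-up tau 3.9 stimuli, plateau 13% below the initial response,
recovery tau 1.2 s).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import adaptation as ad
from . import decoders as dec
from . import directional as dr
from .circular import circular_correlation, wrap_pc
from .cohort import (CohortConfig, NoiseConfig, PopulationResponse,
                     emulate_recorded_cohort, select_units, simulate_experiment,
                     tone_response_matrix)
from .dynamic_model import DynamicPopulation, ModelConfig, make_population
from .stimuli import (PairConfig, TuningConfig, generate_biased_pair_set,
                      generate_biased_tuning_set, schedule_table)


@dataclass
class RunConfig:
    pair: PairConfig = field(default_factory=PairConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(directional_fraction=2 / 3))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    outdir: str = "run_output"
    kernel_width: float = 1.5  # directional-decoder distance kernel, st
    run_tuning: bool = True
    select_alpha: float = 0.05


@dataclass
class RunReport:
    metrics: dict
    paths: dict
    config: dict


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def train_matrix_from_bias(resp: PopulationResponse):
    """Responses to the distinct bias tones (gap-copies averaged).

    Returns (events, matrix): one row per distinct bias tone (240 for
    the default design), trial- and gap-averaged, in Hz.
    """
    events, mat = tone_response_matrix(resp, roles=("bias",))
    key = events["bias_id"] + "#" + events["event_index"].astype(str)
    events = events.assign(_key=key)
    agg_rows, agg_mat = [], []
    for k, g in events.groupby("_key", sort=False):
        agg_rows.append(g.iloc[0])
        agg_mat.append(mat[g.index.to_numpy()].mean(axis=0))
    ev = pd.DataFrame(agg_rows).drop(columns=["_key"]).reset_index(drop=True)
    return ev, np.vstack(agg_mat)


def empirical_shepard_tuning(train_events: pd.DataFrame, train_mat: np.ndarray,
                             res: float = 0.5):
    """Per-cell Shepard tuning from the distinct bias tones.

    Returns (grid, curves) with curves (n_cells, n_grid): mean response
    per pitch bin of width ``res`` st.
    """
    n_bins = int(round(12.0 / res))
    grid = res * np.arange(n_bins)
    bins = np.floor(wrap_pc(train_events["pitch_class"].to_numpy()) / res).astype(int) % n_bins
    curves = np.full((train_mat.shape[1], n_bins), np.nan)
    for b in range(n_bins):
        m = bins == b
        if m.any():
            curves[:, b] = train_mat[m].mean(axis=0)
    # fill unsampled bins by circular interpolation
    if np.isnan(curves).any():
        for i in range(curves.shape[0]):
            row = curves[i]
            good = ~np.isnan(row)
            if good.all():
                continue
            gg = np.concatenate([grid[good], grid[good][:1] + 12.0])
            vv = np.concatenate([row[good], row[good][:1]])
            curves[i] = np.interp(grid, gg, vv)
    return grid, curves


def decode_stage(resp: PopulationResponse,
                 test_roles: tuple = ("test1", "test2")) -> dict:
    """Fit the pitch-circle decoder and measure bias-induced shifts.

    The decoder trains on the distinct bias tones and is applied to the
    ``test_roles`` events of the same experiment.
    """
    train_ev, train_mat = train_matrix_from_bias(resp)
    embed = dec.fit_pca_circle(train_mat, train_ev["pitch_class"].to_numpy())
    train_decoded = dec.decode_pitch(embed, train_mat)
    train_corr = circular_correlation(train_ev["pitch_class"].to_numpy(), train_decoded)
    test_ev, test_mat = tone_response_matrix(resp, roles=test_roles)
    pca_decoded = dec.decode_pitch(embed, test_mat)
    pca_shift = dec.measure_bias_shift(test_ev, pca_decoded)
    # population vector: empirical best pc and max rate per cell
    grid, curves = empirical_shepard_tuning(train_ev, train_mat)
    best_pcs = grid[np.argmax(curves, axis=1)]
    max_rates = np.maximum(train_mat.max(axis=0), 1e-9)
    prior = dec.estimate_bf_prior(best_pcs)
    pv_decoded = np.array([
        dec.population_vector_decode(test_mat[e], best_pcs, max_rates, prior)[0]
        for e in range(test_mat.shape[0])
    ])
    pv_shift = dec.measure_bias_shift(test_ev, pv_decoded)
    return {
        "embedding": embed, "train_events": train_ev, "train_matrix": train_mat,
        "train_circular_correlation": float(train_corr),
        "pca_shift": pca_shift, "popvec_shift": pv_shift,
        "tuning_grid": grid, "tuning_curves": curves,
    }


def directional_stage(resp: PopulationResponse, kernel_width: float = 1.5,
                      n_lags: int = 5, window: float = 1.5,
                      n_di_bins: int = 7) -> dict:
    """Estimate SSTRFs, DIs, directional predictions and the
    bias-differential response map with its near-tone test."""
    est = dr.estimate_sstrf(resp, n_lags=n_lags)
    di_tbl = dr.directionality_table(est)
    test_ev, test_mat = tone_response_matrix(resp, roles=("test1", "test2"))
    pred = dr.directional_prediction_table(
        test_ev, test_mat, di_tbl["DI"].to_numpy(), di_tbl["com_pc"].to_numpy(),
        kernel_width=kernel_width)
    samples = dr.differential_samples(test_ev, test_mat, di_tbl["DI"].to_numpy(),
                                      di_tbl["com_pc"].to_numpy())
    dmap = dr.differential_response_map(samples, n_di_bins=n_di_bins)
    p_near = dr.near_tone_test(samples, window=window)
    # per-instance accuracy (every gap/randomization separately) and
    # per-condition accuracy (mean D over the 8 base x direction cells)
    acc = (pred.groupby(["role", "bias_length"])["correct"].mean()
           .rename("accuracy").reset_index())
    cond = (pred.assign(signed=pred["D"] * pred["expected_sign"])
            .groupby(["role", "bias_length", "base_pc", "bias_direction"])["signed"]
            .mean().reset_index())
    cond["correct"] = cond["signed"] > 0
    cond_acc = (cond.groupby(["role", "bias_length"])["correct"].mean()
                .rename("accuracy").reset_index())
    return {"sstrf": est, "di_table": di_tbl, "predictions": pred,
            "accuracy": acc, "condition_accuracy": cond_acc,
            "condition_table": cond, "map": dmap, "near_tone_p": float(p_near),
            "samples": samples}


def ablation_suite(seed: int, n_cells: int = 500, peak_hz: float = 20.0,
                   pair_cfg: PairConfig | None = None) -> dict:
    """Near-tone significance contrasts across model ablations.

    Reproduces the model comparison of the differential-response
    analysis: the full model (adaptation + directional thirds), an
    ablation without adaptation, and one without directional cells.
    Run on the symmetric model population with deterministic rates and
    the constructed directionality (the question is whether near-tone
    differential activity depends on direction class, so the class is
    known by construction); without adaptation the matched-condition
    differential is exactly zero and the test is undefined (reported
    as nan, i.e. no significant dependence).
    """
    from .dynamic_model import preferred_tone_response, simulate_rates

    if pair_cfg is None:
        pair_cfg = PairConfig()
    noise = NoiseConfig(repetitions=1, mode="rate", tail=0.5)
    out = {}
    variants = {
        "full": ModelConfig(n_cortical=n_cells, directional_fraction=2 / 3),
        "no_adaptation": ModelConfig(n_cortical=n_cells, directional_fraction=2 / 3,
                                     f_a=0.0),
        "no_directional": ModelConfig(n_cortical=n_cells, directional_fraction=0.0),
    }
    seqs = generate_biased_pair_set(pair_cfg, seed)
    for name, mcfg in variants.items():
        pop = make_population(mcfg)
        pref = preferred_tone_response(pop)
        pop.rate_gain = peak_hz / np.where(pref > 0, pref, 1.0)
        resp = simulate_experiment(seqs, pop, noise, seed + 11)
        di_tbl = dr.directionality_table(dr.model_sstrf(pop))
        ev, mat = tone_response_matrix(resp, roles=("test1", "test2"))
        samples = dr.differential_samples(ev, mat, di_tbl["DI"].to_numpy(),
                                          di_tbl["com_pc"].to_numpy())
        out[name] = dr.near_tone_test(samples)
    return out


def adaptation_stage(resp_pair: PopulationResponse,
                     resp_tuning: PopulationResponse | None = None,
                     regions=None, soa: float = 0.15) -> dict:
    """Adaptation build-up, response types, recovery, biased tuning."""
    psth = ad.position_psth(resp_pair, roles=("bias",), window="onset",
                            max_position=10)
    pop_psth = psth.mean(axis=0)
    tau_build, plateau, pop_fit = buildup_fit(pop_psth, soa=soa)
    # response types from the window-averaged PSTH (the three 50 ms
    # windows behave alike and are averaged into one label)
    psth_all = np.mean([ad.position_psth(resp_pair, roles=("bias",), window=w,
                                         max_position=10)
                        for w in ("onset", "sustained", "offset")], axis=0)
    labels = []
    for i in range(psth_all.shape[0]):
        try:
            labels.append(ad.classify_response_type(psth_all[i][1:], soa=soa).label)
        except (ValueError, RuntimeError):
            labels.append("flat")
    labels = np.asarray(labels)
    frac_adapting = float(np.mean(labels == "adapting"))
    times, rates = ad.spontaneous_recovery_trace(resp_pair)
    tau_rec, rec_diag = ad.recovery_fit(times, rates)
    out = {
        "population_fit": pop_fit,
        "buildup_tau_stimuli": float(pop_fit.tau_stimuli),
        "plateau_fraction": float(plateau),
        "fraction_adapting": frac_adapting,
        "recovery_tau_s": tau_rec, "recovery_diag": rec_diag,
        "position_psth": pop_psth,
    }
    if resp_tuning is not None and regions is not None:
        comp = ad.biased_tuning(resp_tuning, regions)
        red_in, red_out = comp.mean_reduction()
        out["tuning_comparison"] = comp
        out["reduction_inside"] = red_in
        out["reduction_outside"] = red_out
    return out


def halfwidth_summary(curves: np.ndarray) -> dict:
    widths, flags = [], []
    for i in range(curves.shape[0]):
        w, degenerate = ad.tuning_halfwidth(curves[i])
        widths.append(w)
        flags.append(degenerate)
    widths = np.asarray(widths)
    ok = ~np.asarray(flags)
    return {"halfwidths": widths, "median_halfwidth": float(np.median(widths[ok]))
            if ok.any() else float("nan")}


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    f_a: float
    f_r: float
    a_max: float
    achieved: dict
    targets: dict
    converged: bool


def f_r_for_recovery(tau_s: float, sample_rate: float = 20.0) -> float:
    """Closed-form recovery fraction per frame for a recovery time
    constant: A decays by (1-F_R) per frame."""
    return float(1.0 - np.exp(-1.0 / (sample_rate * tau_s)))


def buildup_fit(psth: np.ndarray, soa: float = 0.15, skip_first: int = 1):
    """Exponential build-up fit of a position PSTH -> (tau, plateau).

    The first tone is excluded from the fit: it is the only one without
    a preceding tone, so the late (150-250 ms) SSTRF lobes of
    directional cells contribute to every onset response except the
    first, producing an initial buildup before the adaptive decay (the
    same feature is visible in recorded population PSTHs).
    """
    fit = ad.classify_response_type(np.asarray(psth, dtype=float)[skip_first:], soa=soa)
    plateau = (fit.initial_rate - fit.asymptote_rate) / fit.initial_rate
    return float(fit.tau_stimuli), float(plateau), fit


def _buildup_stats(model_cfg: ModelConfig, seed: int = 0, n_cells: int = 300,
                   baseline_hz: float = 2.0, n_rand: int = 16,
                   n_runs: int = 1) -> tuple[float, float]:
    """Deterministic population build-up statistics (tau in stimuli,
    plateau fraction) for the L=10 bias sequences.

    Measured on a cohort with the default marginals (widths, peak
    rates, adapting fraction, directional thirds) but without trial
    noise, so the statistic matches what the full noisy experiment
    converges to.
    """
    from .stimuli import to_spectrogram
    from .dynamic_model import simulate_rates

    pair = PairConfig(gaps=(0.5,), bias_lengths=(10,), n_randomizations=n_rand)
    psth = np.zeros(10)
    n_seq = 0
    for run in range(n_runs):
        sub = (int(seed) * 17 + run * 101) & 0x7FFFFFFF
        seqs = generate_biased_pair_set(pair, sub)
        pop, _ = emulate_recorded_cohort(CohortConfig(n=n_cells), model_cfg, sub + 1)
        for seq in seqs:
            spec = to_spectrogram(seq, model_cfg.sample_rate, model_cfg.n_bins)
            rates, eff, _ = simulate_rates(pop, spec, return_efficacy=True)
            hz = rates + baseline_hz * eff
            onsets = [int(np.floor(e.onset * model_cfg.sample_rate + 1e-6))
                      for e in seq.events if e.role == "bias"]
            psth += np.array([hz[f].mean() for f in onsets])
            n_seq += 1
    psth /= n_seq
    tau, plateau, _ = buildup_fit(psth, soa=pair.soa)
    return tau, plateau


def calibrate(model_cfg: ModelConfig, targets: dict, seed: int = 0,
              n_cells: int = 300, n_rand: int = 16, n_runs: int = 1) -> CalibrationResult:
    """Tune the adaptation parameters to match the target statistics.

    ``targets`` keys: ``tau_recovery_s`` fixes F_R in closed form;
    ``tau_build_stimuli`` and ``plateau_fraction`` drive a search over
    the adaptation gain F_A and the maximal depression fraction A_max,
    minimizing summed squared log-errors of the simulated build-up
    statistics.  An empty target set is ill-posed and raises.
    """
    if not targets:
        raise ValueError("calibration needs at least one target")
    f_r = model_cfg.f_r
    if "tau_recovery_s" in targets:
        f_r = f_r_for_recovery(targets["tau_recovery_s"], model_cfg.sample_rate)
    cfg = replace(model_cfg, f_r=f_r)
    build_targets = {k: targets[k] for k in ("tau_build_stimuli", "plateau_fraction")
                     if k in targets}
    f_a, a_max = cfg.f_a, cfg.a_max
    achieved: dict = {}
    converged = True
    if build_targets:
        def loss(x):
            log_fa, log_amax = x
            if log_amax > 0:  # A_max cannot exceed 1
                return 1e3 + log_amax
            c = replace(cfg, f_a=float(np.exp(np.clip(log_fa, np.log(1e-3), 0.0))),
                        a_max=float(np.exp(log_amax)))
            tau, plateau = _buildup_stats(c, seed, n_cells=n_cells, n_rand=n_rand,
                                          n_runs=n_runs)
            err = 0.0
            if "tau_build_stimuli" in build_targets and tau > 0:
                err += np.log(tau / build_targets["tau_build_stimuli"]) ** 2
            if "plateau_fraction" in build_targets and plateau > 0:
                err += np.log(plateau / build_targets["plateau_fraction"]) ** 2
            return err if np.isfinite(err) else 1e6

        res = minimize(loss, x0=[np.log(cfg.f_a), np.log(min(cfg.a_max, 0.5))],
                       method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 1e-5, "maxfev": 80})
        f_a = float(np.exp(np.clip(res.x[0], np.log(1e-3), 0.0)))
        a_max = float(np.exp(min(res.x[1], 0.0)))
        converged = bool(res.success)
        tau, plateau = _buildup_stats(replace(cfg, f_a=f_a, a_max=a_max), seed,
                                      n_cells=n_cells, n_rand=n_rand, n_runs=n_runs)
        achieved.update({"tau_build_stimuli": tau, "plateau_fraction": plateau})
    achieved["tau_recovery_s"] = -1.0 / (cfg.sample_rate * np.log(1.0 - f_r))
    return CalibrationResult(f_a=f_a, f_r=f_r, a_max=a_max, achieved=achieved,
                             targets=dict(targets), converged=converged)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write a report bundle."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = generate_biased_pair_set(cfg.pair, cfg.seed)
    schedule_table(seqs).to_csv(out / "stimulus_schedule.csv", index=False)
    pop, meta = emulate_recorded_cohort(cfg.cohort, cfg.model, cfg.seed + 1)
    resp = simulate_experiment(seqs, pop, cfg.noise, cfg.seed + 2, neuron_meta=meta)
    kept = select_units(resp, alpha=cfg.select_alpha)
    resp_sel = resp.subset(kept)
    decode = decode_stage(resp_sel)
    decode["pca_shift"].table.to_csv(out / "pca_shift.csv", index=False)
    decode["popvec_shift"].table.to_csv(out / "popvec_shift.csv", index=False)
    direct = directional_stage(resp_sel, kernel_width=cfg.kernel_width,
                               n_lags=cfg.model.n_lags)
    direct["di_table"].to_csv(out / "directionality.csv", index=False)
    direct["predictions"].to_csv(out / "directional_predictions.csv", index=False)
    resp_tuning = None
    if cfg.run_tuning:
        tseqs = generate_biased_tuning_set(cfg.tuning, cfg.seed + 3)
        resp_tuning = simulate_experiment(tseqs, pop, cfg.noise, cfg.seed + 4,
                                          neuron_meta=meta).subset(kept)
    adapt = adaptation_stage(resp_sel, resp_tuning,
                             regions=cfg.tuning.regions if cfg.run_tuning else None,
                             soa=cfg.pair.soa)
    hw = halfwidth_summary(decode["tuning_curves"])
    shift_by_len = decode["pca_shift"].mean_shift(by="bias_length")
    metrics = {
        "n_sequences": len(seqs),
        "n_units_selected": int(kept.size),
        "train_circular_correlation": decode["train_circular_correlation"],
        "mean_shift_pca": decode["pca_shift"].mean_shift(),
        "mean_shift_popvec": decode["popvec_shift"].mean_shift(),
        "shift_by_length": {str(k): float(v) for k, v in shift_by_len["mean"].items()},
        "buildup_tau_stimuli": adapt["buildup_tau_stimuli"],
        "plateau_fraction": adapt["plateau_fraction"],
        "fraction_adapting": adapt["fraction_adapting"],
        "recovery_tau_s": adapt["recovery_tau_s"],
        "near_tone_p": direct["near_tone_p"],
        "median_halfwidth": hw["median_halfwidth"],
        "directional_accuracy": {
            f"{r.role}_L{int(r.bias_length)}": float(r.accuracy)
            for r in direct["accuracy"].itertuples()
        },
    }
    if "reduction_inside" in adapt:
        metrics["reduction_inside"] = adapt["reduction_inside"]
        metrics["reduction_outside"] = adapt["reduction_outside"]
    paths = {p.name: str(p) for p in out.glob("*.csv")}
    report = RunReport(metrics=metrics, paths=paths,
                       config=_config_to_dict(cfg))
    with open(out / "report.json", "w") as fh:
        json.dump({"metrics": metrics, "paths": paths, "config": report.config},
                  fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _config_to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: _config_to_dict(getattr(cfg, f.name))
                for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [_config_to_dict(v) for v in cfg]
    if isinstance(cfg, (np.floating, np.integer)):
        return cfg.item()
    return cfg
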