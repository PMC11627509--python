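"""Synthetic population recordings: trial noise, unit selection, cohorts.

Turns noiseless dynamic-model rates into trial-resolved spike counts in
50 ms bins (Poisson noise, 10 repetitions by default) with per-neuron
metadata, emulating the structure of an awake-recording dataset: a
heterogeneous cohort of tuned single units (halfwidths down to 2-3
semitones, ~91% adapting) responding to the two stimulus paradigms.

Spontaneous activity is transmitted through the same depressing
synapses as the driven response, so it is scaled by the current
synaptic efficacy and recovers after a bias sequence with the model's
recovery time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamic_model import (AdaptationState, DynamicPopulation, ModelConfig,
                            make_population, preferred_tone_response, simulate_rates)
from .stimuli import ToneSequence, alignment_table, to_spectrogram


@dataclass
class NoiseConfig:
    repetitions: int = 10
    gain: float = 1.0  # multiplies driven firing rates
    baseline_hz: float = 2.0  # spontaneous rate at full synaptic efficacy
    mode: Literal["spikes", "rate"] = "spikes"
    tail: float = 3.0  # s of silence appended after each sequence

    def __post_init__(self):
        if self.gain < 0 or self.baseline_hz < 0:
            raise ValueError("gain and baseline must be nonnegative")


@dataclass
class PopulationResponse:
    """Trial x neuron x 50 ms-bin responses with stimulus alignment.

    ``counts`` holds spike counts (spike mode) or firing rates in Hz
    (rate mode).  ``alignment`` has one row per time bin with the
    sequence/event bookkeeping needed by every downstream analysis.
    """

    counts: np.ndarray  # (n_trials, n_neurons, n_bins)
    bin_width: float  # s
    alignment: pd.DataFrame
    neuron_meta: pd.DataFrame
    mode: str = "spikes"

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def trial_mean_hz(self) -> np.ndarray:
        """Trial-averaged firing rates, (n_neurons, n_bins), Hz."""
        m = self.counts.mean(axis=0)
        return m / self.bin_width if self.mode == "spikes" else m

    def subset(self, unit_idx) -> "PopulationResponse":
        unit_idx = np.asarray(unit_idx)
        return PopulationResponse(
            counts=self.counts[:, unit_idx, :],
            bin_width=self.bin_width,
            alignment=self.alignment,
            neuron_meta=self.neuron_meta.iloc[unit_idx].reset_index(drop=True),
            mode=self.mode,
        )


def simulate_experiment(sequences: Sequence[ToneSequence], pop: DynamicPopulation,
                        noise_cfg: NoiseConfig, seed: int,
                        neuron_meta: pd.DataFrame | None = None) -> PopulationResponse:
    """Simulate trial-resolved responses to a set of tone sequences.

    The adaptation state is reset before each sequence (the paradigms
    separate trials by several seconds of silence, ample for recovery).
    Per-trial counts are Poisson around rate * bin_width; spontaneous
    activity is the baseline rate scaled by the synaptic efficacy.
    """
    cfg = pop.cfg
    sr = cfg.sample_rate
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rate_blocks, align_blocks = [], []
    offset = 0
    for seq in sequences:
        total = seq.duration + noise_cfg.tail
        spec = to_spectrogram(seq, sr, cfg.n_bins, total_duration=total)
        rates, eff, _ = simulate_rates(pop, spec, return_efficacy=True)
        hz = noise_cfg.gain * rates + noise_cfg.baseline_hz * eff
        align = alignment_table(seq, sr, n_frames=spec.n_frames)
        align["seq_id"] = seq.seq_id
        align["bias_id"] = seq.bias_id
        align["global_frame"] = align["frame"] + offset
        bm = seq.bias_meta
        align["gap"] = bm.gap if bm else np.nan
        align["bias_direction"] = bm.direction if bm else ""
        align["bias_length"] = bm.length if bm else 0
        align["bias_center"] = bm.center if bm else np.nan
        align["base_pc"] = seq.base_pc
        align["randomization"] = seq.randomization
        # time since the offset of the last bias-role tone (recovery clock)
        bias_events = [e for e in seq.events if e.role in ("bias", "lead_in")]
        if bias_events:
            bias_end = max(e.onset + e.tone.duration for e in bias_events)
            align["t_after_bias"] = align["frame"] / sr - bias_end
        else:
            align["t_after_bias"] = np.nan
        last_tone_end = max(e.onset + e.tone.duration for e in seq.events)
        align["t_after_tone"] = align["frame"] / sr - last_tone_end
        rate_blocks.append(hz)
        align_blocks.append(align)
        offset += spec.n_frames
    hz_all = np.vstack(rate_blocks)  # (n_bins_total, n_neurons)
    alignment = pd.concat(align_blocks, ignore_index=True)
    lam = hz_all.T  # (n_neurons, n_bins_total)
    if noise_cfg.mode == "rate":
        counts = np.repeat(lam[None, :, :], noise_cfg.repetitions, axis=0)
    else:
        counts = rng.poisson(lam[None, :, :] * (1.0 / sr),
                             size=(noise_cfg.repetitions,) + lam.shape).astype(np.int16)
    if neuron_meta is None:
        neuron_meta = pd.DataFrame({
            "id": np.arange(pop.n_cells),
            "best_pc": pop.best_pcs,
            "direction_class": pop.directions,
        })
    return PopulationResponse(counts=counts, bin_width=1.0 / sr, alignment=alignment,
                              neuron_meta=neuron_meta, mode=noise_cfg.mode)


def tone_response_matrix(resp: PopulationResponse, roles=("bias",),
                         window_bins: tuple[int, int] = (0, 2)) -> tuple[pd.DataFrame, np.ndarray]:
    """Trial-averaged response to each tone event of the given roles.

    Returns (events, matrix) with matrix shape (n_events, n_neurons) in
    Hz, averaging counts over the during-tone offset bins in
    ``window_bins`` (half-open, 0 = onset bin).
    """
    al = resp.alignment
    mask = al["role"].isin(roles) & (al["offset_bin"] >= window_bins[0]) \
        & (al["offset_bin"] < window_bins[1])
    sub = al[mask]
    mean_hz = resp.trial_mean_hz()  # (n_neurons, n_bins)
    groups = sub.groupby(["seq_id", "event_index"], sort=False)
    rows, mats = [], []
    for (seq_id, ev), g in groups:
        frames = g["global_frame"].to_numpy()
        mats.append(mean_hz[:, frames].mean(axis=1))
        first = g.iloc[0]
        rows.append({
            "seq_id": seq_id, "bias_id": first["bias_id"], "event_index": ev,
            "role": first["role"], "pitch_class": first["pitch_class"],
            "position": first["position"], "gap": first["gap"],
            "bias_direction": first["bias_direction"],
            "bias_length": first["bias_length"], "bias_center": first["bias_center"],
            "base_pc": first["base_pc"], "randomization": first["randomization"],
        })
    return pd.DataFrame(rows), np.vstack(mats)


# ---------------------------------------------------------------------------
# Unit selection
# ---------------------------------------------------------------------------


def select_units(resp: PopulationResponse, alpha: float = 0.05,
                 alpha_driven: float = 0.05) -> np.ndarray:
    """Indices of units that are auditory-driven and Shepard-tuned.

    Driven: one-sided Wilcoxon signed-rank of per-trial mean driven
    counts against per-trial mean spontaneous counts.  Tuned: Kruskal-
    Wallis of per-trial tone responses across pitch classes (1 st bins),
    p < alpha.  Thresholds are deliberately not critical.
    """
    if resp.n_trials < 2:
        raise ValueError("unit selection needs at least 2 repetitions")
    al = resp.alignment
    driven_frames = al.loc[al["role"].isin(["bias", "lead_in", "probe", "test1", "test2"])
                           & (al["offset_bin"] < 2), "global_frame"].to_numpy()
    spont_frames = al.loc[(al["event_index"] == -1) & (al["offset_bin"] >= 6),
                          "global_frame"].to_numpy()
    tone_al = al[al["role"].isin(["bias", "lead_in", "probe"]) & (al["offset_bin"] == 0)]
    pc_groups = tone_al.groupby(np.floor(tone_al["pitch_class"]).astype(int))
    keep = []
    for i in range(resp.n_neurons):
        drv = resp.counts[:, i, driven_frames].mean(axis=1)
        spn = resp.counts[:, i, spont_frames].mean(axis=1) if spont_frames.size else np.zeros(resp.n_trials)
        diff = drv - spn
        if np.allclose(diff, 0):
            continue
        p_drv = stats.wilcoxon(diff, alternative="greater").pvalue
        if p_drv >= alpha_driven:
            continue
        samples = []
        for _, g in pc_groups:
            frames = g["global_frame"].to_numpy()
            samples.append(resp.counts[:, i, frames].reshape(-1))
        samples = [s for s in samples if s.size]
        if len(samples) < 2:
            continue
        if alpha >= 1.0:
            keep.append(i)
            continue
        try:
            p_kw = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            continue
        if p_kw < alpha:
            keep.append(i)
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# Cohort emulation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Marginals of the emulated recorded cohort."""

    n: int = 662
    width_log_mean: float = -0.693  # lognormal on sigma (st): median ~0.5
    width_log_sd: float = 0.25
    width_clip: tuple[float, float] = (0.5, 3.0)
    peak_rate_log_mean: float = 3.0  # lognormal on peak rate (Hz): median ~20
    peak_rate_log_sd: float = 0.5
    adapting_fraction: float = 0.91
    direction_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # none, up, down
    bf_jitter: bool = True


def emulate_recorded_cohort(cohort_cfg: CohortConfig, model_cfg: ModelConfig,
                            seed: int) -> tuple[DynamicPopulation, pd.DataFrame]:
    """Draw a heterogeneous model population matching cohort marginals.

    Best pitch classes are equally spaced with jitter (near-uniform
    coverage of the octave); widths and peak rates are lognormal;
    direction classes follow ``direction_mix``; a Bernoulli
    ``adapting_fraction`` of cells adapt (non-adapting cells have their
    adaptation gain set to zero).  Per-cell rate gains convert model
    units into firing rates calibrated to each cell's peak rate.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    n = cohort_cfg.n
    best = 12.0 * np.arange(n) / n
    if cohort_cfg.bf_jitter:
        best = np.mod(best + rng.uniform(-6.0 / n, 6.0 / n, size=n), 12.0)
    rng.shuffle(best)
    widths = np.clip(rng.lognormal(cohort_cfg.width_log_mean, cohort_cfg.width_log_sd, n),
                     *cohort_cfg.width_clip)
    peak_rates = rng.lognormal(cohort_cfg.peak_rate_log_mean, cohort_cfg.peak_rate_log_sd, n)
    mix = np.asarray(cohort_cfg.direction_mix, dtype=float)
    mix = mix / mix.sum()
    directions = rng.choice(np.array(["none", "up", "down"], dtype=object), size=n, p=mix)
    adapting = rng.random(n) < cohort_cfg.adapting_fraction
    cfg = replace(model_cfg, n_cortical=n)
    pop = make_population(cfg, best_pcs=best, directions=directions, widths=widths)
    pop.adapt_scale = adapting.astype(float)
    pref = preferred_tone_response(pop)
    pop.rate_gain = peak_rates / np.where(pref > 0, pref, 1.0)
    true_di = np.where(directions == "up", 1.0, np.where(directions == "down", -1.0, 0.0))
    meta = pd.DataFrame({
        "id": np.arange(n),
        "best_pc": best,
        "width": widths,
        "peak_rate": peak_rates,
        "direction_class": directions,
        "true_DI": true_di,
        "adapting": adapting,
    })
    return pop, meta
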