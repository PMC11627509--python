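"""Directionality: SSTRF estimation, DI, directional decoding, maps.

A cell's Shepard spectro-temporal receptive field (SSTRF) is estimated
by reverse correlation (ridge regression of the 50 ms-binned response on
the lagged pitch-class spectrogram).  The directionality index DI is the
asymmetry of the previous-stimulus column of the max-normalized SSTRF
around the best pitch class of the current-stimulus column:

    DI = sum_{d<0} SSTRF(t2, BF + d) - sum_{d>0} SSTRF(t2, BF + d)

Positive DI marks upward-selective cells (they respond more to the
current tone when the previous tone was *below* it).

The **directional decoder** predicts the perceived step direction of a
tone directly from activity: each cell's response is weighted by its DI
and a circular kernel of the distance between its SSTRF center of mass
and the tone; the sign of the average predicts ascending (+) versus
descending (-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV

from .circular import circular_distance, circular_step, pc_to_angle, wrap_pc
from .cohort import PopulationResponse
from .tuning import von_mises_kappa


@dataclass
class EstimatedSSTRF:
    """Per-cell lag x pitch-bin filters estimated by reverse correlation."""

    weights: np.ndarray  # (n_cells, n_lags, n_pitch)
    pitch_values: np.ndarray  # (n_pitch,) pitch class of each column
    lag_s: float  # lag bin width, s


def estimate_sstrf(resp: PopulationResponse, n_lags: int = 5,
                   roles=("bias", "lead_in"), alphas=None) -> EstimatedSSTRF:
    """Reverse-correlate each neuron's response with the tone history.

    Design: lagged one-hot pitch-class history of the bias tones (one
    column per (lag, pitch bin), z-normalized), restricted to response
    bins during a stimulus.  Ridge regression with leave-one-out
    generalized cross-validation handles the collinear lagged design.
    """
    al = resp.alignment
    sr = 1.0 / resp.bin_width
    n_bins_pitch = 24
    pitch_vals = 12.0 * np.arange(n_bins_pitch) / n_bins_pitch
    # reconstruct the one-hot stimulus per global frame
    n_frames = len(al)
    stim = np.zeros((n_frames, n_bins_pitch))
    tone_rows = al[al["event_index"] >= 0]
    idx = tone_rows["global_frame"].to_numpy()
    bins = (np.round(tone_rows["pitch_class"].to_numpy() * n_bins_pitch / 12.0).astype(int)
            % n_bins_pitch)
    stim[idx, bins] = 1.0
    # response bins: during-stimulus frames of the requested roles; lag
    # history must not cross sequence boundaries
    seq_codes = pd.factorize(al["seq_id"])[0]
    use = (al["role"].isin(roles) & (al["offset_bin"] < 2)).to_numpy()
    frames = np.nonzero(use)[0]
    ok = []
    for f in frames:
        if f - (n_lags - 1) >= 0 and seq_codes[f - (n_lags - 1)] == seq_codes[f]:
            ok.append(f)
    frames = np.asarray(ok)
    X = np.stack([stim[frames - lag] for lag in range(n_lags)], axis=1)  # (n, L, P)
    X = X.reshape(frames.size, n_lags * n_bins_pitch)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xz = (X - mu) / sd
    Y = resp.trial_mean_hz()[:, frames].T  # (n, n_cells)
    if alphas is None:
        alphas = np.logspace(-2, 3, 12)
    model = RidgeCV(alphas=alphas)
    model.fit(Xz, Y)
    coefs = (model.coef_ / sd[None, :]).reshape(-1, n_lags, n_bins_pitch)
    return EstimatedSSTRF(weights=coefs, pitch_values=pitch_vals, lag_s=resp.bin_width)


def model_sstrf(pop) -> EstimatedSSTRF:
    """Wrap a model population's constructed SSTRFs in the estimated
    container (columns indexed by mid-level best pitch class)."""
    mid_pcs = pop.midlevel.best_pcs
    return EstimatedSSTRF(weights=pop.sstrfs.copy(), pitch_values=mid_pcs,
                          lag_s=1.0 / pop.cfg.sample_rate)


@dataclass
class DirectionalityIndex:
    DI: float
    best_pc_lag0: float
    com_pc: float


def directionality_index(weights: np.ndarray, pitch_values: np.ndarray,
                         t1_lags=(0, 1), t2_lags=(3, 4)) -> DirectionalityIndex:
    """DI of one SSTRF (lag x pitch).

    t1 = current-stimulus lags, t2 = previous-stimulus lags (the pause
    lag between them is excluded).  The filter is first normalized to
    its maximum; the half-octave tie bin (|d| = 6) is excluded.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] < 2:
        raise ValueError("need at least 2 lag bins")
    peak = np.max(np.abs(w))
    wn = w / peak if peak > 0 else w
    t1_lags = [l for l in t1_lags if l < wn.shape[0]]
    t2_lags = [l for l in t2_lags if l < wn.shape[0]]
    t1 = wn[t1_lags].mean(axis=0)
    t2 = wn[t2_lags].mean(axis=0) if t2_lags else np.zeros_like(t1)
    bf = float(pitch_values[int(np.argmax(t1))])
    delta = circular_step(bf, pitch_values)
    below = (delta < 0) & (np.abs(delta) < 6.0 - 1e-9)
    above = (delta > 0) & (np.abs(delta) < 6.0 - 1e-9)
    di = float(t2[below].sum() - t2[above].sum())
    pos = np.clip(wn.sum(axis=0), 0.0, None)
    z = np.sum(pos * np.exp(1j * pc_to_angle(pitch_values)))
    com = float(wrap_pc(np.angle(z) * 12.0 / (2.0 * np.pi))) if np.abs(z) > 1e-12 else bf
    return DirectionalityIndex(DI=di, best_pc_lag0=bf, com_pc=com)


def directionality_table(est: EstimatedSSTRF, t1_lags=(0, 1), t2_lags=(3, 4)) -> pd.DataFrame:
    rows = []
    for i in range(est.weights.shape[0]):
        r = directionality_index(est.weights[i], est.pitch_values, t1_lags, t2_lags)
        rows.append({"id": i, "DI": r.DI, "best_pc_lag0": r.best_pc_lag0,
                     "com_pc": r.com_pc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Directional decoding
# ---------------------------------------------------------------------------


def directional_decode(responses: np.ndarray, dis: np.ndarray, com_pcs: np.ndarray,
                       tone_pc: float, kernel_width: float = 1.5) -> float:
    """Signed directional score D(S); positive predicts "ascending".

    D = sum_i w_i * DI_i * f_i(S) / sum_i w_i with w_i a period-12 von
    Mises kernel of the circular distance between the cell's SSTRF
    center of mass and the tone.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        raise ValueError("empty population")
    k = von_mises_kappa(kernel_width)
    w = np.exp(k * (np.cos(pc_to_angle(np.asarray(com_pcs)) - pc_to_angle(tone_pc)) - 1.0))
    return float(np.sum(w * np.asarray(dis) * responses) / np.sum(w))


def expected_percept_sign(role: str, bias_direction: str) -> float:
    """Defined percept label for a test tone, as a step sign.

    The first tone's step is heard *away* from the bias side (an
    up-bias sits above the first tone, so the step into it is heard as
    descending); the second tone's step bridges the bias (ascending for
    an up-bias).  Encoded as a fixed labeling rule from the human
    psychophysics.
    """
    if bias_direction not in ("up", "down"):
        raise ValueError("bias_direction must be 'up' or 'down'")
    up = bias_direction == "up"
    if role == "test1":
        return -1.0 if up else 1.0
    if role == "test2":
        return 1.0 if up else -1.0
    raise ValueError("role must be test1 or test2")


def directional_prediction_table(events: pd.DataFrame, responses: np.ndarray,
                                 dis: np.ndarray, com_pcs: np.ndarray,
                                 kernel_width: float = 1.5) -> pd.DataFrame:
    """Directional decodes and correctness for a set of test tones."""
    rows = []
    for e, (_, row) in enumerate(events.iterrows()):
        d = directional_decode(responses[e], dis, com_pcs, row["pitch_class"],
                               kernel_width)
        expect = expected_percept_sign(row["role"], row["bias_direction"])
        rows.append({**row.to_dict(), "D": d, "expected_sign": expect,
                     "correct": bool(np.sign(d) == expect)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bias-differential response map
# ---------------------------------------------------------------------------


@dataclass
class DifferentialMap:
    grid: np.ndarray  # (n_di_bins, n_rel_bins) mean differential response
    counts: np.ndarray
    sem: np.ndarray
    di_edges: np.ndarray
    rel_edges: np.ndarray
    samples: pd.DataFrame  # per (cell, tone instance) differentials


def differential_samples(events: pd.DataFrame, responses: np.ndarray,
                         dis: np.ndarray, com_pcs: np.ndarray,
                         exclude_recent_bias_s: float | None = 0.25,
                         tone_duration: float = 0.1) -> pd.DataFrame:
    """Per-cell response differences between matched up/down-bias
    conditions ("bias locally above tone" minus "below"), for both test
    tones (each cell contributes at two relative locations).

    Test tones whose preceding *bias* tone started within
    ``exclude_recent_bias_s`` of the tone onset are excluded: there the
    bias tone still falls inside the SSTRF's temporal span, so the
    up/down difference contains a residual sensory transient rather
    than the adaptation state.  (The second tone is never affected: its
    predecessor is the first test tone, identical in both conditions.)
    """
    keys = ["base_pc", "bias_length", "gap", "randomization", "role"]
    ev = events.reset_index(drop=True)
    if exclude_recent_bias_s is not None:
        contaminated = (ev["role"] == "test1") & \
            (ev["gap"] + tone_duration < exclude_recent_bias_s - 1e-9)
        responses = np.asarray(responses)[~contaminated.to_numpy()]
        ev = ev[~contaminated].reset_index(drop=True)
    rows = []
    for key_vals, g in ev.groupby(keys):
        if set(g["bias_direction"]) != {"up", "down"}:
            continue
        iu = g.index[g["bias_direction"] == "up"][0]
        idn = g.index[g["bias_direction"] == "down"][0]
        tone_pc = float(g.loc[iu, "pitch_class"])
        role = g.loc[iu, "role"]
        # which condition has the bias locally above this tone?
        up_above = circular_step(tone_pc, float(g.loc[iu, "bias_center"])) > 0
        diff = (responses[iu] - responses[idn]) if up_above else (responses[idn] - responses[iu])
        rel = circular_step(tone_pc, com_pcs)
        for i in range(diff.size):
            rows.append({"cell": i, "DI": dis[i], "rel_pc": rel[i],
                         "diff": diff[i], "role": role, "tone_pc": tone_pc})
    return pd.DataFrame(rows)


def differential_response_map(samples: pd.DataFrame, n_di_bins: int = 7,
                              rel_bin_width: float = 1.0) -> DifferentialMap:
    """Bin the per-cell differentials into (DI, relative-pc) cells."""
    di = samples["DI"].to_numpy()
    rel = samples["rel_pc"].to_numpy()
    diff = samples["diff"].to_numpy()
    di_edges = np.linspace(di.min(), di.max() + 1e-12, n_di_bins + 1)
    rel_edges = np.arange(-6.0, 6.0 + rel_bin_width / 2, rel_bin_width)
    grid = np.full((n_di_bins, rel_edges.size - 1), np.nan)
    sem = np.full_like(grid, np.nan)
    counts = np.zeros_like(grid, dtype=int)
    di_idx = np.clip(np.digitize(di, di_edges) - 1, 0, n_di_bins - 1)
    rel_idx = np.clip(np.digitize(rel, rel_edges) - 1, 0, rel_edges.size - 2)
    for b in range(n_di_bins):
        for r in range(rel_edges.size - 1):
            m = (di_idx == b) & (rel_idx == r)
            counts[b, r] = m.sum()
            if counts[b, r]:
                vals = diff[m]
                grid[b, r] = vals.mean()
                sem[b, r] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return DifferentialMap(grid=grid, counts=counts, sem=sem,
                           di_edges=di_edges, rel_edges=rel_edges, samples=samples)


def near_tone_test(samples: pd.DataFrame, window: float = 1.5,
                   mode: str = "sign", n_di_bins: int = 7) -> float:
    """One-way ANOVA of near-tone differentials across directionality.

    Restricted to cells whose SSTRF center of mass lies within
    ``window`` st of the tone; one sample per cell (its mean
    differential).  ``mode="sign"`` compares ascending-preferring
    (DI > 0) against descending-preferring (DI < 0) cells;
    ``mode="bins"`` uses ``n_di_bins`` equal-width DI bins.  Returns
    the p-value (nan when fewer than 2 groups are populated).
    """
    near = samples[np.abs(samples["rel_pc"]) <= window]
    if near.empty:
        return float("nan")
    per_cell = near.groupby("cell").agg(DI=("DI", "mean"), diff=("diff", "mean"))
    di = per_cell["DI"].to_numpy()
    vals = per_cell["diff"].to_numpy()
    if mode == "sign":
        groups = [vals[di > 0], vals[di < 0]]
    else:
        edges = np.linspace(samples["DI"].min(), samples["DI"].max() + 1e-12,
                            n_di_bins + 1)
        idx = np.clip(np.digitize(di, edges) - 1, 0, n_di_bins - 1)
        groups = [vals[idx == b] for b in range(n_di_bins)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return float("nan")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) < 1e-12:  # no differential activity at all
        return float("nan")
    return float(stats.f_oneway(*groups).pvalue)
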