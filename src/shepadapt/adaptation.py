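"""Adaptation analyses: PSTHs, response types, recovery, biased tuning.

The bias-sequence PSTH of each cell is split into onset (0-50 ms),
sustained (50-100 ms) and offset (100-150 ms) windows per tone (the
three 50 ms windows tile the 150 ms stimulus onset asynchrony).  The
sequence of rates over bias position is fitted with an exponential
r(k) = a + b * exp(-k / tau); a cell is *adapting* when the asymptote
lies below the initial rate, *facilitating* when above.

Tuning-curve adaptation is analyzed from the biased-tuning paradigm:
probe tones give the adapted tuning per bias region (0.5 st grid); the
first stimuli of every sequence, pooled across conditions, give the
unadapted baseline (1 st grid, circularly interpolated to 0.5 st).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .circular import wrap_pc
from .cohort import PopulationResponse

WINDOW_NAMES = ("onset", "sustained", "offset")


def psth_windows(resp: PopulationResponse, roles=("bias",),
                 max_position: int | None = None) -> pd.DataFrame:
    """Trial-mean rates per (cell, bias position, window).

    Windows are the single 50 ms bins at offsets 0, 1, 2 re tone onset
    (onset / sustained / offset); with a 150 ms SOA they tile the
    inter-onset interval exactly.
    """
    al = resp.alignment
    mean_hz = resp.trial_mean_hz()
    # offset window (bin 2) falls in the pause, where event_index == -1
    rows = []
    tone_mask = al["role"].isin(roles) & (al["offset_bin"].isin([0, 1]))
    pause_mask = (al["event_index"] == -1) & (al["offset_bin"] == 2)
    for wname, obin in zip(WINDOW_NAMES, (0, 1, 2)):
        if obin < 2:
            sub = al[al["role"].isin(roles) & (al["offset_bin"] == obin)]
        else:
            # the offset bin belongs to the pause after the tone; recover
            # the owning event from the preceding onset frame
            sub = al[pause_mask].copy()
            owner = al.set_index("global_frame")
            prev = owner.reindex(sub["global_frame"] - 2)
            sub = sub.assign(role=prev["role"].to_numpy(),
                             position=prev["position"].to_numpy(),
                             pitch_class=prev["pitch_class"].to_numpy())
            sub = sub[sub["role"].isin(roles)]
        for (seq_id, pos), g in sub.groupby(["seq_id", "position"]):
            if max_position is not None and pos >= max_position:
                continue
            frames = g["global_frame"].to_numpy()
            rates = mean_hz[:, frames].mean(axis=1)
            for cell in range(resp.n_neurons):
                rows.append((seq_id, int(pos), wname, cell, rates[cell]))
    return pd.DataFrame(rows, columns=["seq_id", "position", "window", "cell", "rate"])


def position_psth(resp: PopulationResponse, roles=("bias",),
                  window: str = "onset", max_position: int | None = None) -> np.ndarray:
    """(n_cells, n_positions) mean rate over sequences, single window.

    Lighter-weight than :func:`psth_windows` for population summaries.
    """
    al = resp.alignment
    obin = WINDOW_NAMES.index(window)
    sub = al[al["role"].isin(roles) & (al["offset_bin"] == 0)]
    mean_hz = resp.trial_mean_hz()
    positions = sorted(sub["position"].unique())
    if max_position is not None:
        positions = [p for p in positions if 0 <= p < max_position]
    n_frames_total = mean_hz.shape[1]
    out = np.empty((resp.n_neurons, len(positions)))
    for k, pos in enumerate(positions):
        # window frame = onset frame + window offset (the offset window
        # is the pause bin, still owned by the preceding tone)
        frames = sub.loc[sub["position"] == pos, "global_frame"].to_numpy() + obin
        frames = frames[frames < n_frames_total]
        out[:, k] = mean_hz[:, frames].mean(axis=1)
    return out


@dataclass
class ResponseTypeResult:
    label: str  # adapting | facilitating | flat
    tau_stimuli: float
    tau_seconds: float
    initial_rate: float
    asymptote_rate: float
    window: str = "combined"
    reliable: bool = True


def _exp_decay(k, a, b, tau):
    return a + b * np.exp(-k / tau)


def classify_response_type(rates: np.ndarray, soa: float = 0.15,
                           window: str = "combined",
                           flat_tol: float = 0.02) -> ResponseTypeResult:
    """Fit r(k) = a + b*exp(-k/tau) over bias position and classify.

    Adapting when the asymptote is below the initial rate, facilitating
    when above; near-equal (within ``flat_tol`` of the initial rate)
    is tie-broken to a "flat" label.  Non-converging fits fall back to
    an endpoint comparison with tau flagged unreliable.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 bias positions")
    k = np.arange(1, r.size + 1, dtype=float)
    p0 = (r[-1], r[0] - r[-1], max(r.size / 2.0, 1e-3))
    reliable = True
    try:
        popt, _ = curve_fit(_exp_decay, k, r, p0=p0,
                            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
                            maxfev=10000)
        a, b, tau = popt
        initial = _exp_decay(1.0, a, b, tau)
    except RuntimeError:
        a, initial, tau = r[-1], r[0], float("nan")
        b = initial - a
        reliable = False
    ref = max(abs(initial), 1e-12)
    if abs(a - initial) < flat_tol * ref:
        label = "flat"
    elif a < initial:
        label = "adapting"
    else:
        label = "facilitating"
    return ResponseTypeResult(label=label, tau_stimuli=float(tau),
                              tau_seconds=float(tau * soa), initial_rate=float(initial),
                              asymptote_rate=float(a), window=window, reliable=reliable)


def _exp_recovery(t, base, c, tau):
    return base - c * np.exp(-t / tau)


def recovery_fit(times: np.ndarray, rates: np.ndarray,
                 degenerate_tol: float = 0.02) -> tuple[float, dict]:
    """Exponential recovery of spontaneous rate toward baseline.

    Fits r(t) = base - c * exp(-t / tau) to rates over time since the
    bias end; returns (tau_seconds, diagnostics).  When there is
    nothing to recover (c below ``degenerate_tol`` of the baseline) the
    result is flagged degenerate and tau is nan.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    base0 = r[-1] if r[-1] > 0 else max(r.max(), 1e-6)
    c0 = max(base0 - r[0], 1e-9)
    try:
        popt, _ = curve_fit(_exp_recovery, t, r, p0=(base0, c0, 1.0),
                            bounds=([0, 0, 1e-3], [np.inf, np.inf, 100.0]), maxfev=10000)
    except RuntimeError:
        return float("nan"), {"degenerate": True, "converged": False}
    base, c, tau = popt
    if c < degenerate_tol * max(base, 1e-12):
        return float("nan"), {"degenerate": True, "converged": True,
                              "baseline": float(base), "depth": float(c)}
    return float(tau), {"degenerate": False, "converged": True,
                        "baseline": float(base), "depth": float(c)}


def spontaneous_recovery_trace(resp: PopulationResponse, t_min: float = 0.3,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Population-mean spontaneous rate vs time since the last tone.

    Uses silent frames at least ``t_min`` s after the final tone of
    each sequence (beyond the SSTRF span, so no driven response
    contaminates the spontaneous rate), binned on the recovery clock.
    """
    al = resp.alignment
    mask = (al["event_index"] == -1) & (al["t_after_tone"] >= t_min)
    sub = al[mask]
    mean_hz = resp.trial_mean_hz()
    tbl = sub.groupby(np.round(sub["t_after_tone"] / resp.bin_width).astype(int))
    times, rates = [], []
    for tk, g in tbl:
        frames = g["global_frame"].to_numpy()
        times.append(tk * resp.bin_width)
        rates.append(mean_hz[:, frames].mean())
    return np.asarray(times), np.asarray(rates)


# ---------------------------------------------------------------------------
# Biased tuning curves
# ---------------------------------------------------------------------------


@dataclass
class TuningComparison:
    """Adapted vs unadapted tuning on a common 0.5 st grid.

    ``adapted``: (n_regions, n_cells, 24); profiles are circularly
    re-centered on each region's bias center before averaging, so grid
    position 0 is the bias center.
    """

    grid: np.ndarray  # 24-point pitch grid (absolute, st)
    unadapted: np.ndarray  # (n_cells, 24)
    adapted: np.ndarray  # (n_regions, n_cells, 24)
    region_centers: np.ndarray
    difference_centered: np.ndarray  # (n_regions, n_cells, 24), unadapted - adapted
    ratio_centered: np.ndarray  # adapted / unadapted (nan-safe)
    rel_grid: np.ndarray  # centered grid, -6..6

    def mean_reduction(self, inside: float = 2.5, outside: float = 3.0):
        """Population-mean reduction inside vs outside the bias."""
        rel = np.abs(np.where(self.rel_grid > 6, self.rel_grid - 12, self.rel_grid))
        mask_in = rel <= inside
        mask_out = rel > outside
        d = np.nanmean(self.difference_centered, axis=(0, 1))
        return float(np.nanmean(d[mask_in])), float(np.nanmean(d[mask_out]))

    def fractional_reduction(self, inside: float = 2.5) -> float:
        """Rate-weighted fractional reduction inside the bias region:
        1 - (summed adapted rate) / (summed unadapted rate), which
        emphasizes the responsive (high-rate) part of the curves."""
        rel = np.abs(np.where(self.rel_grid > 6, self.rel_grid - 12, self.rel_grid))
        mask_in = rel <= inside
        with np.errstate(invalid="ignore", divide="ignore"):
            un_c = self.difference_centered / (1.0 - self.ratio_centered)
        diff = self.difference_centered[:, :, mask_in]
        un = un_c[:, :, mask_in]
        ok = np.isfinite(diff) & np.isfinite(un) & (un > 0)
        return float(diff[ok].sum() / un[ok].sum())


def _circ_interp(grid_from: np.ndarray, values: np.ndarray, grid_to: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation on the pitch circle."""
    gf = np.concatenate([grid_from, grid_from[:1] + 12.0])
    vv = np.concatenate([values, values[:1]])
    return np.interp(np.mod(grid_to, 12.0), gf, vv)


def biased_tuning(resp: PopulationResponse, regions, n_unadapted: int = 5,
                  window_bins: tuple[int, int] = (0, 2)) -> TuningComparison:
    """Adapted and unadapted tuning curves from the tuning paradigm.

    Adapted curves come from the probe tones of each bias region (24 x
    0.5 st grid); the unadapted baseline pools the first ``n_unadapted``
    stimuli of every sequence across conditions (1 st resolution,
    interpolated to the probe grid).
    """
    from .cohort import tone_response_matrix

    grid = 12.0 * np.arange(24) / 24.0
    probes, pm = tone_response_matrix(resp, roles=("probe",), window_bins=window_bins)
    first, fm = tone_response_matrix(resp, roles=("lead_in",), window_bins=window_bins)
    early = (first["position"] < n_unadapted).to_numpy()
    first = first[early].reset_index(drop=True)
    fm = fm[early]
    n_cells = pm.shape[1]
    # unadapted: pool across conditions at 1 st, interpolate to 0.5 st
    coarse = np.arange(12) + 0.5
    un_coarse = np.full((n_cells, 12), np.nan)
    fbins = np.floor(wrap_pc(first["pitch_class"].to_numpy())).astype(int) % 12
    for b in range(12):
        m = fbins == b
        if m.any():
            un_coarse[:, b] = fm[m].mean(axis=0)
    if np.isnan(un_coarse).any():
        col_mean = np.nanmean(un_coarse, axis=0)
        fill = np.nanmean(un_coarse)
        for b in range(12):
            if np.isnan(col_mean[b]):
                un_coarse[:, b] = fill
        un_coarse = np.where(np.isnan(un_coarse), np.nanmean(un_coarse, axis=1)[:, None],
                             un_coarse)
    unadapted = np.vstack([_circ_interp(coarse, un_coarse[i], grid) for i in range(n_cells)])
    region_list = list(regions)
    centers = np.array([wrap_pc((lo + hi) / 2.0) for lo, hi in region_list])
    adapted = np.full((len(region_list), n_cells, 24), np.nan)
    probe_bins = (np.round(probes["pitch_class"].to_numpy() * 2.0).astype(int)) % 24
    for ri, (lo, hi) in enumerate(region_list):
        center = centers[ri]
        in_region = np.isclose(probes["bias_center"].to_numpy().astype(float),
                               float(center))
        for b in range(24):
            m = in_region & (probe_bins == b)
            if m.any():
                adapted[ri, :, b] = pm[m].mean(axis=0)
    diff = unadapted[None, :, :] - adapted
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(unadapted[None, :, :] > 0, adapted / unadapted[None, :, :], np.nan)
    # re-center each region so that grid index 0 is the bias center
    rel_grid = np.arange(24) * 0.5
    diff_c = np.empty_like(diff)
    ratio_c = np.empty_like(ratio)
    for ri, center in enumerate(centers):
        shift = int(np.round(center * 2.0)) % 24
        diff_c[ri] = np.roll(diff[ri], -shift, axis=1)
        ratio_c[ri] = np.roll(ratio[ri], -shift, axis=1)
    return TuningComparison(grid=grid, unadapted=unadapted, adapted=adapted,
                            region_centers=centers, difference_centered=diff_c,
                            ratio_centered=ratio_c, rel_grid=rel_grid)


# ---------------------------------------------------------------------------
# Tuning halfwidth
# ---------------------------------------------------------------------------


def tuning_halfwidth(curve: np.ndarray, grid: np.ndarray | None = None,
                     ) -> tuple[float, bool]:
    """Half-height tuning width on a circular grid, in semitones.

    Threshold = f_min + (f_max - f_min)/2.  Walks circularly from the
    minimum's location in both directions to the nearest threshold
    crossings (linear interpolation); the halfwidth is the octave minus
    the below-threshold arc.  Flat curves return (12, degenerate=True).
    The estimate is conservative: weakly modulated cells get large
    halfwidths.  Exactly invariant under affine rate transforms.
    """
    f = np.asarray(curve, dtype=float)
    n = f.size
    if grid is None:
        grid = 12.0 * np.arange(n) / n
    fmin, fmax = f.min(), f.max()
    if fmax - fmin <= 1e-12 * max(abs(fmax), 1.0):
        return 12.0, True
    thresh = fmin + (fmax - fmin) / 2.0
    imin = int(np.argmin(f))

    def _walk(direction: int) -> float:
        """Arc length from the minimum to the first upward crossing."""
        arc = 0.0
        i = imin
        for _ in range(n):
            j = (i + direction) % n
            seg = np.mod(direction * (grid[j] - grid[i]), 12.0)
            if f[j] > thresh:
                frac = (thresh - f[i]) / (f[j] - f[i])
                return arc + frac * seg
            arc += seg
            i = j
        return arc

    below_arc = _walk(+1) + _walk(-1)
    return float(12.0 - below_arc), False
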