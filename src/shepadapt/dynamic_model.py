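"""Dynamic two-layer encoding model with synaptic depression.

Architecture: a pitch-class spectrogram S(t, phi) drives a mid-level
layer of von Mises units (T_j); each cortical cell integrates the
mid-level activity through a Shepard spectro-temporal receptive field
(SSTRF, lag x mid-unit weights at 50 ms lag bins) whose thalamo-cortical
synapses depress locally:

    R_i(t) = (1/J) * sum_j sum_tau SSTRF_i(tau, j) * (1 - A_ij(t)) * T_j(t - tau)

The depression state A_ij accumulates with the synapse's own drive and
recovers exponentially:

    A_ij <- clip( (A_ij + F_A * d_ij * (1 - A_ij)) * (1 - F_R), 0, A_max )

where d_ij is the max-normalized SSTRF weight times the peak-normalized
mid-level activity, summed over lags.  With no drive, A decays by a
factor (1 - F_R) per 50 ms frame, i.e. exponential recovery with time
constant 1 / (sample_rate * F_R) seconds (to first order).

Directional cells carry an extra late von Mises lobe (150-250 ms lags,
peak 0.25 of the main lobe) placed *above* the best pitch class for
downward-preferring cells and *below* it for upward-preferring cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circular import wrap_pc
from .stimuli import PitchClassSpectrogram
from .tuning import MidLevelLayer, tuning_matrix

#: recovery fraction per frame matching a 1.2 s recovery time constant at 20 Hz
F_R_DEFAULT = float(1.0 - np.exp(-1.0 / (20.0 * 1.2)))

#: adaptation gain and depression ceiling calibrated so the population
#: onset response over a 7 Hz bias train decays with tau ~= 3.9 stimuli
#: to a plateau ~13% below the initial response (see pipeline.calibrate)
F_A_DEFAULT = 0.062424
A_MAX_DEFAULT = 0.335401


@dataclass
class ModelConfig:
    """Configuration of the dynamic model population."""

    n_cortical: int = 100
    n_midlevel: int = 48
    n_bins: int = 24
    sigma_mid: float = 0.85  # st, mid-level tuning width (sets adaptation spread)
    sigma_cortical: float = 0.5  # st, cortico-midlevel weight profile width
    sample_rate: float = 20.0  # Hz (50 ms frames)
    n_lags: int = 5
    f_a: float = F_A_DEFAULT
    f_r: float = F_R_DEFAULT
    a_max: float = A_MAX_DEFAULT
    directional_fraction: float = 0.0  # fraction of cells that are directional
    directional_peak: float = 0.25  # late lobe peak re main lobe
    directional_lag_window: tuple[float, float] = (0.150, 0.250)  # s
    directional_offset: float = 3.0  # st between best pc and late lobe center
    directional_width: float = 1.0  # st, late lobe width
    lag1_scale: float = 1.0  # weight of the previous-frame column re lag 0
    printed_update: bool = False  # use the non-accumulating textbook update
    seed: int = 0

    def __post_init__(self):
        for name in ("f_a", "f_r", "directional_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def build_directional_sstrf(best_pc: float, direction: str, cfg: ModelConfig) -> np.ndarray:
    """Construct one cell's SSTRF (n_lags x n_midlevel).

    Lags 0..1 (0-100 ms, the tone's own frames) carry the cell's tuning
    over mid-unit best pitch classes; for directional cells, lags inside
    the configured 150-250 ms window carry a von Mises lobe of peak
    ``directional_peak``, centered ``directional_offset`` st above the
    best pc for down cells and below it for up cells (circular wrap).
    """
    mid_pcs = 12.0 * np.arange(cfg.n_midlevel) / cfg.n_midlevel
    w = np.zeros((cfg.n_lags, cfg.n_midlevel))
    main = tuning_matrix([best_pc], cfg.sigma_cortical, mid_pcs, "peak_one")[0]
    w[0] = main
    if cfg.n_lags > 1:
        w[1] = cfg.lag1_scale * main
    if direction in ("up", "down"):
        sgn = 1.0 if direction == "down" else -1.0
        center = wrap_pc(best_pc + sgn * cfg.directional_offset)
        late = cfg.directional_peak * tuning_matrix([center], cfg.directional_width,
                                                    mid_pcs, "peak_one")[0]
        dt = 1.0 / cfg.sample_rate
        lo, hi = cfg.directional_lag_window
        for lag in range(cfg.n_lags):
            if lo - 1e-9 <= lag * dt < hi - 1e-9:
                w[lag] = late
    return w


@dataclass
class DynamicPopulation:
    """A population of model cortical cells with their SSTRFs."""

    cfg: ModelConfig
    sstrfs: np.ndarray  # (n_cells, n_lags, n_midlevel)
    best_pcs: np.ndarray  # (n_cells,)
    directions: np.ndarray  # (n_cells,) of {"up","down","none"}
    midlevel: MidLevelLayer
    adapt_scale: np.ndarray | None = None  # per-cell multiplier on F_A
    rate_gain: np.ndarray | None = None  # per-cell Hz scaling of the raw rate

    @property
    def n_cells(self) -> int:
        return self.sstrfs.shape[0]

    def connection_weights(self) -> np.ndarray:
        """Lag-summed synaptic weights (n_cells, n_midlevel)."""
        return self.sstrfs.sum(axis=1)


def make_population(cfg: ModelConfig, best_pcs=None, directions=None,
                    widths=None) -> DynamicPopulation:
    """Build a model population.

    Defaults: best pitch classes equally spaced over [0, 12); direction
    classes split as evenly as possible into up/down/none according to
    ``directional_fraction`` (the directional cells are split half up,
    half down, interleaved across the pitch axis so every class covers
    the octave).
    """
    n = cfg.n_cortical
    if best_pcs is None:
        best_pcs = 12.0 * np.arange(n) / n
    best_pcs = np.asarray(best_pcs, dtype=float)
    n = best_pcs.size
    if directions is None:
        n_dir = int(round(n * cfg.directional_fraction))
        labels = np.array(["none"] * n, dtype=object)
        dir_idx = np.linspace(0, n - 1, n_dir).round().astype(int) if n_dir else []
        for k, i in enumerate(dir_idx):
            labels[i] = "up" if k % 2 == 0 else "down"
        directions = labels
    directions = np.asarray(directions, dtype=object)
    if widths is None:
        widths = np.full(n, cfg.sigma_cortical)
    widths = np.asarray(widths, dtype=float)
    sstrfs = np.empty((n, cfg.n_lags, cfg.n_midlevel))
    for i in range(n):
        cell_cfg = replace(cfg, sigma_cortical=float(widths[i]))
        sstrfs[i] = build_directional_sstrf(float(best_pcs[i]), str(directions[i]), cell_cfg)
    mid = MidLevelLayer(cfg.n_midlevel, cfg.sigma_mid, cfg.n_bins)
    return DynamicPopulation(cfg=cfg, sstrfs=sstrfs, best_pcs=best_pcs,
                             directions=directions, midlevel=mid)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class AdaptationState:
    """Synaptic depression state A_ij in [0, A_max]."""

    A: np.ndarray  # (n_cells, n_midlevel)

    @classmethod
    def zeros(cls, pop: DynamicPopulation) -> "AdaptationState":
        return cls(A=np.zeros((pop.n_cells, pop.cfg.n_midlevel)))


def step_dynamic_model(state: AdaptationState, pop: DynamicPopulation,
                       T_history: np.ndarray) -> tuple[np.ndarray, AdaptationState]:
    """Advance the model by one 50 ms frame.

    ``T_history``: (n_lags, n_midlevel) mid-level activity, row 0 = the
    current frame, row tau = tau frames in the past.  Returns the rates
    computed with the *current* depression state, then the updated state.
    """
    cfg = pop.cfg
    W = pop.sstrfs  # (N, L, J)
    if T_history.shape[0] < cfg.n_lags:
        raise ValueError("T_history must hold at least n_lags frames")
    Tlag = T_history[:cfg.n_lags]  # (L, J)
    U = np.einsum("nlj,lj->nj", W, Tlag)  # drive per synapse, unnormalized
    rates = ((1.0 - state.A) * U).sum(axis=1) / cfg.n_midlevel
    rates = np.clip(rates, 0.0, None)
    # drive for the depression update: max-normalized SSTRF weights times
    # peak-normalized mid-level activity (T * n_bins), summed over lags
    wmax = W.reshape(W.shape[0], -1).max(axis=1)
    wmax = np.where(wmax > 0, wmax, 1.0)
    d = np.einsum("nlj,lj->nj", W, Tlag * cfg.n_bins) / wmax[:, None]
    fa = cfg.f_a if pop.adapt_scale is None else cfg.f_a * pop.adapt_scale[:, None]
    if cfg.printed_update:
        A_new = state.A * (1.0 - fa * d) * (1.0 - cfg.f_r)
    else:
        A_new = (state.A + fa * d * (1.0 - state.A)) * (1.0 - cfg.f_r)
    A_new = np.clip(A_new, 0.0, cfg.a_max)
    return rates, AdaptationState(A=A_new)


def simulate_rates(pop: DynamicPopulation, spec: PitchClassSpectrogram,
                   state: AdaptationState | None = None,
                   return_efficacy: bool = False):
    """Run the model over a whole spectrogram.

    Returns rates (n_frames, n_cells) in model units (times ``rate_gain``
    in Hz when the population carries one), and optionally the per-cell
    synaptic efficacy trace (weighted mean of 1 - A_ij), which scales
    spontaneous activity transmitted through the same synapses.
    """
    cfg = pop.cfg
    if spec.n_bins != cfg.n_bins:
        raise ValueError("spectrogram pitch-bin count does not match the model")
    T = pop.midlevel.activity_trace(spec.frames)  # (n_frames, J)
    n_frames = T.shape[0]
    if state is None:
        state = AdaptationState.zeros(pop)
    rates = np.empty((n_frames, pop.n_cells))
    eff = np.empty((n_frames, pop.n_cells)) if return_efficacy else None
    wbar = pop.connection_weights()
    wbar_sum = wbar.sum(axis=1)
    wbar_sum = np.where(wbar_sum > 0, wbar_sum, 1.0)
    Tpad = np.vstack([np.zeros((cfg.n_lags - 1, T.shape[1])), T])
    for t in range(n_frames):
        hist = Tpad[t:t + cfg.n_lags][::-1]  # row 0 = current frame
        if eff is not None:
            eff[t] = (wbar * (1.0 - state.A)).sum(axis=1) / wbar_sum
        rates[t], state = step_dynamic_model(state, pop, hist)
    if pop.rate_gain is not None:
        rates = rates * pop.rate_gain[None, :]
    if return_efficacy:
        return rates, eff, state
    return rates, state


def preferred_tone_response(pop: DynamicPopulation) -> np.ndarray:
    """Peak unadapted model response of each cell to its own preferred
    tone (used to convert model units into firing rates)."""
    cfg = pop.cfg
    peaks = np.empty(pop.n_cells)
    mid = pop.midlevel
    for i in range(pop.n_cells):
        frame = np.zeros(cfg.n_bins)
        frame[int(np.round(pop.best_pcs[i] * cfg.n_bins / 12.0)) % cfg.n_bins] = 1.0
        Tj = mid.activity(frame)
        # tone lasts 2 frames; response peaks when lags 0..1 are filled
        resp = (pop.sstrfs[i, :2].sum(axis=0) * Tj).sum() / cfg.n_midlevel
        peaks[i] = resp
    return peaks
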