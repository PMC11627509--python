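"""Non-dynamic adaptation models on an idealized von Mises population.

Three phenomenological variants of how a biasing stimulus range reduces
subsequent responses:

* **local** - each stimulus is scaled by how prominent it was in the
  recent history: R_i(S) = (1 - A0 * S_bias(S)) * M_i(S).  Purely
  stimulus-specific; the whole population is scaled identically for a
  given test stimulus, so decoded pitch is unchanged.
* **global** - each *cell* is scaled by the overlap of its tuning curve
  with the bias: R_i(S) = (1 - A_i) * M_i(S), with A_i the tuning-
  weighted mean of the bias profile.  Cells near the bias adapt most,
  so decoding is repelled from the bias.
* **spread** - local adaptation at the synapses of a distributed
  mid-level representation: the cortical response integrates mid-level
  activity through per-connection depression.  Reduces tuning curves
  locally *and* repels decoding - the variant consistent with both the
  encoding and decoding observations.

The population here is a continuous, noiseless idealization (N cells,
best pitch classes equally spaced over the octave, area-normalized
tuning); the bias is an idealized profile over pitch class in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .circular import circular_distance, wrap_pc
from .tuning import MidLevelLayer, tuning_matrix

_GRID_N = 1200  # numeric integration grid over the octave


@dataclass
class StaticPopulation:
    """Idealized cortical population with area-one von Mises tuning."""

    n_cells: int = 100
    width: float = 1.0  # semitones

    def __post_init__(self):
        self.best_pcs = 12.0 * np.arange(self.n_cells) / self.n_cells
        self._grid = 12.0 * np.arange(_GRID_N) / _GRID_N
        self._curves = tuning_matrix(self.best_pcs, self.width, self._grid, "area_one")

    def response(self, pc) -> np.ndarray:
        """Unadapted responses of all cells to a single tone: (..., n_cells)."""
        return tuning_matrix(self.best_pcs, self.width, np.atleast_1d(pc), "area_one").T


def boxcar_bias_profile(center: float, width: float = 5.0) -> Callable:
    """Indicator of the bias range (circular boxcar), values in {0, 1}."""

    def profile(pc):
        return (circular_distance(pc, center) <= width / 2.0).astype(float)

    return profile


def _check_a0(a0: float) -> None:
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("A0 must lie in [0, 1]")


@dataclass
class AdaptedStatic:
    """Adapted response function per cell: response(pc) -> (n_pc, n_cells)."""

    pop: StaticPopulation
    response: Callable
    per_cell_adaptation: np.ndarray | None = None  # A_i for the global model


def adapt_local(pop: StaticPopulation, bias_profile: Callable, a0: float = 0.8) -> AdaptedStatic:
    """Purely stimulus-specific adaptation (no transfer across stimuli)."""
    _check_a0(a0)

    def response(pc):
        pcs = np.atleast_1d(np.asarray(pc, dtype=float))
        scale = 1.0 - a0 * np.asarray(bias_profile(pcs), dtype=float)
        return scale[:, None] * pop.response(pcs)

    return AdaptedStatic(pop=pop, response=response)


def adapt_global(pop: StaticPopulation, bias_profile: Callable, a0: float = 0.8) -> AdaptedStatic:
    """Whole-tuning-curve scaling by tuning/bias overlap.

    A_i = A0 * (integral of S_bias * M_i) / (integral of M_i); the
    normalization by the tuning-curve area keeps A_i in [0, A0] exactly.
    """
    _check_a0(a0)
    prof = np.asarray(bias_profile(pop._grid), dtype=float)
    overlap = (pop._curves * prof[None, :]).sum(axis=1) / pop._curves.sum(axis=1)
    a_i = a0 * overlap

    def response(pc):
        pcs = np.atleast_1d(np.asarray(pc, dtype=float))
        return (1.0 - a_i)[None, :] * pop.response(pcs)

    return AdaptedStatic(pop=pop, response=response, per_cell_adaptation=a_i)


def adapt_spread(pop: StaticPopulation, midlevel: MidLevelLayer,
                 bias_profile: Callable, a0: float = 0.8) -> AdaptedStatic:
    """Local adaptation with a distributed mid-level representation.

    The cortical response is mid-level activity weighted by connection
    strengths M_i(j) and per-connection adaptation 1 - A(j), with
    A(j) = A0 * (tuning-weighted mean of the bias profile under M_j).
    """
    _check_a0(a0)
    grid = pop._grid
    # mid-level curves on the fine grid (peak-normalized)
    Mj = tuning_matrix(midlevel.best_pcs, midlevel.width, grid, "peak_one")
    prof = np.asarray(bias_profile(grid), dtype=float)
    a_j = a0 * (Mj * prof[None, :]).sum(axis=1) / Mj.sum(axis=1)
    # cortico-midlevel connection strengths: cell i's tuning over mid BFs
    Wij = tuning_matrix(pop.best_pcs, pop.width, midlevel.best_pcs, "peak_one")

    def response(pc, adapted=True):
        pcs = np.atleast_1d(np.asarray(pc, dtype=float))
        # point stimulus -> mid-level activity T_j(S) = M_j(S)
        Tj = tuning_matrix(midlevel.best_pcs, midlevel.width, pcs, "peak_one").T
        eff = (1.0 - a_j)[None, :] if adapted else 1.0
        return (Tj * eff) @ Wij.T / midlevel.n_units

    return AdaptedStatic(pop=pop, response=response, per_cell_adaptation=None)


def unadapted_spread_response(pop: StaticPopulation, midlevel: MidLevelLayer):
    """Unadapted counterpart of :func:`adapt_spread` (A == 0)."""
    zero = lambda pc: np.zeros_like(np.atleast_1d(np.asarray(pc, dtype=float)))
    return adapt_spread(pop, midlevel, zero, a0=0.0)


def decoded_shift_suite(bases=(0.0, 3.0, 6.0, 9.0), directions=("up", "down"),
                        a0: float = 0.8, bias_width: float = 5.0,
                        bias_offset: float = 3.0, n_cells: int = 100,
                        width: float = 1.0, n_mid: int = 48,
                        grid_n: int = 480) -> "pd.DataFrame":
    """Decoded-shift sign suite over the 8 (base x direction) conditions.

    For each condition the bias profile is a 5 st boxcar centered
    ``bias_offset`` st above (up) or below (down) the test tone; the
    test tone is population-vector decoded under each adaptation
    variant and compared against the *unadapted* decode of the same
    population (removing the decoder's discretization bias), signed so
    positive points away from the bias.
    """
    import pandas as pd
    from .circular import circular_step
    from .decoders import population_vector_decode

    pop = StaticPopulation(n_cells=n_cells, width=width)
    mid = MidLevelLayer(n_mid, width)
    grid = np.linspace(0, 12, grid_n, endpoint=False)
    mr_vm = pop.response(grid).max(axis=0)
    un_sp = unadapted_spread_response(pop, mid)
    mr_sp = un_sp.response(grid).max(axis=0)

    def _decode(model, pc, mr):
        r = model.response(np.array([pc]))[0]
        out, _ = population_vector_decode(r, pop.best_pcs, mr, None)
        return out

    unadapted_vm = adapt_local(pop, lambda p: np.zeros_like(np.atleast_1d(
        np.asarray(p, dtype=float))), 0.0)
    rows = []
    for base in bases:
        ref_vm = _decode(unadapted_vm, base, mr_vm)
        ref_sp = _decode(un_sp, base, mr_sp)
        for direction in directions:
            sgn = 1.0 if direction == "up" else -1.0
            center = float(np.mod(base + sgn * bias_offset, 12.0))
            prof = boxcar_bias_profile(center, bias_width)
            models = {
                "local": (adapt_local(pop, prof, a0), mr_vm, ref_vm),
                "global": (adapt_global(pop, prof, a0), mr_vm, ref_vm),
                "spread": (adapt_spread(pop, mid, prof, a0), mr_sp, ref_sp),
            }
            for name, (model, mr, ref) in models.items():
                dec_pc = _decode(model, base, mr)
                shift = -sgn * circular_step(ref, dec_pc)
                rows.append({"model": name, "base_pc": base, "direction": direction,
                             "shift_away": float(shift)})
    return pd.DataFrame(rows)
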