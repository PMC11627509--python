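"""Von Mises tuning curves on the pitch circle.

Each model neuron is tuned to a best pitch class phi_i with width
sigma_i (semitones); the curve is a period-12 von Mises function

    M_i(phi) = exp( cos(2*pi/12 * (phi - phi_i)) / ((2*pi/12) * sigma_i)**2 ) / M_total

with M_total chosen either so the curve integrates to 1 over the octave
("area_one", used by the idealized non-dynamic models) or so its peak is
1 ("peak_one", used by the dynamic model's mid-level layer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import i0

from .circular import wrap_pc

_SCALE = 2.0 * np.pi / 12.0


def von_mises_kappa(width: float) -> float:
    """Concentration parameter for a tuning width in semitones."""
    if width <= 0:
        raise ValueError("tuning width must be positive")
    return 1.0 / (_SCALE * width) ** 2


@dataclass(frozen=True)
class VonMisesTuning:
    """Period-12 von Mises tuning curve."""

    best_pc: float
    width: float  # semitones
    peak_rate: float = 1.0
    normalization: Literal["area_one", "peak_one"] = "area_one"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("tuning width must be positive")

    @property
    def kappa(self) -> float:
        return von_mises_kappa(self.width)

    def __call__(self, pc) -> np.ndarray:
        k = self.kappa
        raw = np.exp(k * np.cos(_SCALE * (np.asarray(pc, dtype=float) - self.best_pc)))
        if self.normalization == "area_one":
            total = 12.0 * i0(k)  # integral of exp(k cos) over one octave
        else:
            total = np.exp(k)
        return self.peak_rate * raw / total

    def halfwidth_analytic(self) -> float:
        """Half-height tuning width: arc where the curve exceeds
        f_min + (f_max - f_min) / 2."""
        k = self.kappa
        # normalized curve g(theta) = exp(k(cos theta - 1)); min at theta=pi
        thresh = (1.0 + np.exp(-2.0 * k)) / 2.0
        c = 1.0 + np.log(thresh) / k
        c = np.clip(c, -1.0, 1.0)
        return 2.0 * np.arccos(c) / _SCALE


def tuning_matrix(best_pcs, width, grid, normalization="peak_one") -> np.ndarray:
    """Curves for many units on a pitch grid: (n_units, n_grid)."""
    best_pcs = np.asarray(best_pcs, dtype=float)[:, None]
    grid = np.asarray(grid, dtype=float)[None, :]
    k = von_mises_kappa(width) if np.isscalar(width) else \
        1.0 / (_SCALE * np.asarray(width, dtype=float)[:, None]) ** 2
    raw = np.exp(k * np.cos(_SCALE * (grid - best_pcs)))
    if normalization == "area_one":
        total = 12.0 * i0(k)
    else:
        total = np.exp(k)
    return raw / total


@dataclass
class MidLevelLayer:
    """Bank of equally spaced, peak-normalized von Mises units.

    Stands in for an intermediate auditory station (e.g. the MGB):
    activity is the tuning-weighted average of a spectrogram frame.
    """

    n_units: int
    width: float  # semitones
    n_bins: int = 24

    def __post_init__(self):
        self.best_pcs = 12.0 * np.arange(self.n_units) / self.n_units
        self.grid = 12.0 * np.arange(self.n_bins) / self.n_bins
        # (n_units, n_bins) peak-normalized curves sampled at the bin centers
        self.M = tuning_matrix(self.best_pcs, self.width, self.grid, "peak_one")

    def activity(self, frame: np.ndarray) -> np.ndarray:
        """Mid-level activity T_j = (1/n_bins) * sum_phi M_j(phi) S(phi)."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape[-1] != self.n_bins:
            raise ValueError("frame length does not match the pitch-bin count")
        return frame @ self.M.T / self.n_bins

    def activity_trace(self, frames: np.ndarray) -> np.ndarray:
        """Vectorized activity for a whole spectrogram: (n_frames, n_units)."""
        return self.activity(frames)
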