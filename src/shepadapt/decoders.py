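"""Population decoding of represented pitch class.

Two decoders read out the pitch class represented by a population
response vector:

* the **PCA circle decoder** - a linear decomposition over the training
  responses (stimuli as examples, neurons as dimensions); the two
  components spanning the pitch circle are selected, a coarse 24-anchor
  circle is built from rank-ordered bins of training stimuli, refined to
  a closed polyline at 0.05 st resolution by linear interpolation, and a
  test response is assigned the pitch label of the nearest polyline
  point;
* the **population-vector decoder** - a complex-domain average of the
  neurons' best pitch classes, weighted by max-normalized activity and
  the inverse occurrence frequency of best pitch classes.

Bias-induced shifts are quantified as the signed circular deviation of
decoded from true pitch class, sign-flipped so that positive points
*away* from the bias center (a repulsive shift is positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .circular import (angle_to_pc, circular_mean_pc, circular_step, pc_to_angle,
                       wrap_pc)

POLYLINE_RES = 0.05  # st


@dataclass
class CircleEmbedding:
    """Fitted 2-D pitch-circle embedding of population responses."""

    mean: np.ndarray  # training mean over stimuli, (n_neurons,)
    components: np.ndarray  # (2, n_neurons) selected linear map
    component_indices: tuple[int, int]
    coords: np.ndarray  # (n_train, 2) training projections
    anchors: np.ndarray  # (n_anchors, 2)
    anchor_pcs: np.ndarray  # (n_anchors,)
    polyline: np.ndarray  # (n_points, 2) closed circular trajectory
    polyline_pcs: np.ndarray  # (n_points,)

    def project(self, response: np.ndarray) -> np.ndarray:
        r = np.asarray(response, dtype=float)
        if r.ndim == 1:
            r = r[None, :]
        return (r - self.mean[None, :]) @ self.components.T


def _circle_fit_quality(coords: np.ndarray, pcs: np.ndarray) -> float:
    """Resultant length of angle-vs-pitch circular regression (max over
    the two possible orientations)."""
    theta = np.arctan2(coords[:, 1], coords[:, 0])
    alpha = pc_to_angle(pcs)
    r_ccw = np.abs(np.mean(np.exp(1j * (theta - alpha))))
    r_cw = np.abs(np.mean(np.exp(1j * (theta + alpha))))
    return float(max(r_ccw, r_cw))


def fit_pca_circle(train: np.ndarray, train_pcs, n_anchors: int = 24,
                   n_candidates: int = 5) -> CircleEmbedding:
    """Fit the pitch-circle embedding on training responses.

    ``train``: (n_stimuli, n_neurons); needs at least 48 stimuli
    spanning the octave.  Components are mean-centered; among the top
    ``n_candidates`` components the pair maximizing circular-fit quality
    is selected (the pitch circle is "typically in the first two" but a
    strong sequence-position component can displace it).  The decoder is
    deliberately not cross-validated: it serves as a reference frame for
    held-out test tones.
    """
    train = np.asarray(train, dtype=float)
    pcs = wrap_pc(np.asarray(train_pcs, dtype=float))
    if train.shape[0] < 2 * n_anchors:
        raise ValueError("need at least 2 stimuli per anchor bin")
    n_comp = min(n_candidates, *train.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(train)
    if n_comp < 2 or pca.explained_variance_[1] <= 1e-12 * pca.explained_variance_[0]:
        raise ValueError("response matrix is degenerate (rank < 2)")
    best_pair, best_q = (0, 1), -np.inf
    for pair in combinations(range(n_comp), 2):
        q = _circle_fit_quality(scores[:, pair], pcs)
        if q > best_q:
            best_q, best_pair = q, pair
    coords = scores[:, best_pair]
    # fix orientation: pitch increases counterclockwise
    theta = np.arctan2(coords[:, 1], coords[:, 0])
    alpha = pc_to_angle(pcs)
    if np.abs(np.mean(np.exp(1j * (theta - alpha)))) < np.abs(np.mean(np.exp(1j * (theta + alpha)))):
        coords = coords * np.array([1.0, -1.0])
    components = pca.components_[list(best_pair)].copy()
    if not np.allclose(coords, (train - pca.mean_) @ components.T):
        components[1] = -components[1]
    # coarse circle: rank-order stimuli by pitch (ties by index), bins of
    # n_train / n_anchors neighbors
    order = np.lexsort((np.arange(pcs.size), pcs))
    per_bin = pcs.size // n_anchors
    anchors, anchor_pcs = [], []
    for b in range(n_anchors):
        idx = order[b * per_bin:(b + 1) * per_bin]
        anchors.append(coords[idx].mean(axis=0))
        anchor_pcs.append(circular_mean_pc(pcs[idx]))
    anchors = np.asarray(anchors)
    anchor_pcs = np.asarray(anchor_pcs)
    poly_pts, poly_pcs = [], []
    for b in range(n_anchors):
        b2 = (b + 1) % n_anchors
        step = circular_step(anchor_pcs[b], anchor_pcs[b2])
        if step <= 0:
            step += 12.0
        n_seg = max(1, int(round(step / POLYLINE_RES)))
        frac = np.arange(n_seg) / n_seg
        poly_pts.append(anchors[b][None, :] * (1 - frac[:, None]) + anchors[b2][None, :] * frac[:, None])
        poly_pcs.append(wrap_pc(anchor_pcs[b] + frac * step))
    return CircleEmbedding(
        mean=pca.mean_, components=components, component_indices=best_pair,
        coords=coords, anchors=anchors, anchor_pcs=anchor_pcs,
        polyline=np.vstack(poly_pts), polyline_pcs=np.concatenate(poly_pcs),
    )


def decode_pitch(embed: CircleEmbedding, response: np.ndarray):
    """Decode pitch class(es) from response vector(s).

    Projects into the fitted plane (centering with the *training* mean)
    and returns the pitch label of the nearest polyline point.
    """
    r = np.asarray(response, dtype=float)
    single = r.ndim == 1
    if single and not np.any(r):
        raise ValueError("all-zero response: projection target undefined")
    pts = embed.project(r)
    d2 = ((pts[:, None, :] - embed.polyline[None, :, :]) ** 2).sum(axis=2)
    out = embed.polyline_pcs[np.argmin(d2, axis=1)]
    return float(out[0]) if single else out


def population_vector_decode(response: np.ndarray, best_pcs: np.ndarray,
                             max_rates: np.ndarray, bf_prior: np.ndarray | None = None,
                             tol: float = 1e-6):
    """Complex-domain population-vector readout of pitch class.

    Each neuron contributes a unit vector at angle 2*pi*best_pc/12
    weighted by its max-normalized rate and the inverse occurrence
    frequency of its best pitch class.  Returns (pc, resultant_length);
    pc is nan (undefined) when activity is uniform enough that the
    resultant cancels.
    """
    response = np.asarray(response, dtype=float)
    max_rates = np.asarray(max_rates, dtype=float)
    if np.any(max_rates <= 0):
        raise ValueError("max_rates must be positive")
    w = response / max_rates
    if bf_prior is None:
        prior = estimate_bf_prior(best_pcs)
    else:
        prior = np.asarray(bf_prior, dtype=float)
    w = w / prior
    z = np.sum(w * np.exp(1j * pc_to_angle(best_pcs)))
    norm = np.sum(np.abs(w))
    if norm == 0 or np.abs(z) / norm < tol:
        return float("nan"), 0.0
    return float(angle_to_pc(np.angle(z))), float(np.abs(z) / norm)


def estimate_bf_prior(best_pcs: np.ndarray, n_bins: int = 12) -> np.ndarray:
    """Per-neuron occurrence frequency of best pitch classes.

    Histogram over ``n_bins`` equal circular bins with add-one
    smoothing; returns P(PC_best) evaluated for each neuron.
    """
    best_pcs = wrap_pc(np.asarray(best_pcs, dtype=float))
    bins = np.floor(best_pcs * n_bins / 12.0).astype(int) % n_bins
    hist = np.bincount(bins, minlength=n_bins).astype(float) + 1.0
    prob = hist / hist.sum()
    return prob[bins]


# ---------------------------------------------------------------------------
# Bias-induced shift
# ---------------------------------------------------------------------------


def bias_side_sign(tone_pc: float, bias_center: float) -> float:
    """+1 if the bias center lies (circularly) above the tone, -1 below."""
    return 1.0 if circular_step(tone_pc, bias_center) > 0 else -1.0


def shift_away_from_bias(true_pc: float, decoded_pc: float, bias_center: float) -> float:
    """Signed decoded shift, positive pointing away from the bias."""
    s = bias_side_sign(true_pc, bias_center)
    return -s * circular_step(true_pc, decoded_pc)


@dataclass
class ShiftResult:
    """Per-test-tone decoded pitch classes and repulsive shifts."""

    table: pd.DataFrame  # one row per decoded test tone

    def mean_shift(self, by=None):
        if by is None:
            return float(self.table["shift_away"].mean())
        return self.table.groupby(by)["shift_away"].agg(["mean", "sem", "count"])

    def sign_by_condition(self, by=("base_pc", "bias_direction")) -> pd.Series:
        """Sign of the mean shift per condition (the 8-case sign suite)."""
        return np.sign(self.table.groupby(list(by))["shift_away"].mean())


def measure_bias_shift(events: pd.DataFrame, decoded_pcs: np.ndarray) -> ShiftResult:
    """Assemble a ShiftResult from decoded test tones.

    ``events`` must carry pitch_class, bias_center and the condition
    factors (role, bias_direction, bias_length, gap, base_pc).
    """
    tbl = events.copy().reset_index(drop=True)
    tbl["decoded_pc"] = np.asarray(decoded_pcs, dtype=float)
    shifts, raw = [], []
    for _, row in tbl.iterrows():
        d = circular_step(row["pitch_class"], row["decoded_pc"])
        raw.append(d)
        shifts.append(shift_away_from_bias(row["pitch_class"], row["decoded_pc"],
                                           row["bias_center"]))
    tbl["shift_raw"] = raw
    tbl["shift_away"] = shifts
    return ShiftResult(table=tbl)
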