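"""Circular arithmetic on the 12-semitone pitch-class circle.

Shepard tones live on a circle: pitch class 12 is identical to pitch
class 0.  Every comparison of pitch classes in this package goes through
the helpers here so that wrap-around is handled in exactly one place.
"""

from __future__ import annotations

import numpy as np

PERIOD = 12.0


def wrap_pc(pc):
    """Map pitch class(es) onto [0, 12)."""
    r = np.mod(pc, PERIOD)
    # np.mod can return the period itself for tiny negative inputs
    r = np.where(r >= PERIOD, 0.0, r)
    return r if np.ndim(r) else float(r)


def circular_step(pc_from, pc_to):
    """Signed minimal circular step from ``pc_from`` to ``pc_to``.

    Returns a value in (-6, +6] semitones.  The half-octave boundary is,
    by fixed convention, reported as +6; callers that care about percept
    direction never rely on this sign, only on the bias side.
    """
    d = np.mod(np.asarray(pc_to, dtype=float) - np.asarray(pc_from, dtype=float), PERIOD)
    d = np.where(d > PERIOD / 2, d - PERIOD, d)
    return d if d.ndim else float(d)


def circular_distance(a, b):
    """Unsigned circular distance in [0, 6]."""
    return np.abs(circular_step(a, b))


def pc_to_angle(pc):
    """Pitch class -> angle in radians (period 12 -> period 2*pi)."""
    return np.asarray(pc, dtype=float) * (2.0 * np.pi / PERIOD)


def angle_to_pc(theta):
    """Angle in radians -> pitch class in [0, 12)."""
    return wrap_pc(np.asarray(theta, dtype=float) * (PERIOD / (2.0 * np.pi)))


def circular_mean_pc(pcs, weights=None):
    """Weighted circular mean of pitch classes, in [0, 12).

    Raises ValueError when the resultant vector is (near) zero, i.e. the
    mean direction is undefined.
    """
    pcs = np.asarray(pcs, dtype=float)
    z = np.exp(1j * pc_to_angle(pcs))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        r = np.sum(w * z)
        norm = np.sum(np.abs(w))
    else:
        r = np.sum(z)
        norm = pcs.size
    if norm == 0 or np.abs(r) / norm < 1e-12:
        raise ValueError("circular mean undefined: resultant vector is zero")
    return float(angle_to_pc(np.angle(r)))


def circular_correlation(pc_a, pc_b):
    """Circular correlation coefficient between two pitch-class samples.

    Fisher-Lee T-linear correlation on the 2*pi-scaled angles (well
    defined even for uniformly spread samples, where a mean direction
    is not); 1.0 means a perfect (rotated) circular relation.
    """
    a = pc_to_angle(np.asarray(pc_a, dtype=float))
    b = pc_to_angle(np.asarray(pc_b, dtype=float))
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    sa, sb = np.sin(da), np.sin(db)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)
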