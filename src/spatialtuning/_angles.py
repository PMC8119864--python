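"""Angle conventions and small circular helpers.

Everything at the package surface is in degrees, [0, 360), counterclockwise
positive, 0° along +x. Signed rotations live in (-180, 180], positive =
counterclockwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap360",
    "wrap180",
    "circdist",
    "circmean_deg",
    "resultant",
]


def wrap360(angle):
    """Wrap angle(s) in degrees into [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def wrap180(angle):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(angle, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def circdist(a, b):
    """Unsigned circular distance in degrees, in [0, 180]."""
    return np.abs(wrap180(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def resultant(angles_deg, weights=None):
    """Mean resultant vector of angles.

    Returns (r, mean_direction_deg) with r in [0, 1]. Weights, if given,
    must be non-negative and not all zero.
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        c, s = np.cos(th).mean(), np.sin(th).mean()
    else:
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("weights sum to zero")
        c = float(np.sum(w * np.cos(th)) / tot)
        s = float(np.sum(w * np.sin(th)) / tot)
    r = float(np.hypot(c, s))
    mean = float(np.rad2deg(np.arctan2(s, c))) % 360.0
    return r, mean


def circmean_deg(angles_deg, weights=None):
    """Weighted circular mean direction in [0, 360)."""
    return resultant(angles_deg, weights)[1]
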