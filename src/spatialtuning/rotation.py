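"""Angular-shift estimation by rotational cross-correlation.

The shift of a cell's preferred firing direction between two sessions (or
two maze compartments) is the circular lag at which the Pearson
correlation between the two tuning curves peaks, searched in 1° steps.
Place-field rotation is estimated the same way in 2D: one session's raw
position samples are rotated about the arena center in 5° steps, re-binned,
and correlated with the other session's map over the bins valid in both.

Shifts are reported as signed angles in (-180, 180], positive =
counterclockwise; argmax ties break toward the smallest absolute shift,
then toward the positive sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Point

from ._angles import circdist, circmean_deg, wrap180
from .maps import RateMap, TuningCurve, _bin_session, _nan_smooth, tuning_curve
from .session import ArenaGeometry, SessionRecording, SpikeTrain

__all__ = [
    "RotationResult",
    "CompartmentShifts",
    "tuning_shift",
    "map_rotation_shift",
    "compartment_tuning_curves",
    "adjacent_compartment_shifts",
    "classify_field_barrier_relation",
    "classify_rotation_response",
    "normalize_shift_sign",
]


@dataclass(frozen=True)
class RotationResult:
    shift: float            # deg, (-180, 180]
    max_corr: float
    min_corr: float
    profile: np.ndarray     # correlation at each candidate angle
    angles: np.ndarray      # candidate angles, deg, same length as profile
    n_overlap: int          # bins entering the comparison


@dataclass(frozen=True)
class CompartmentShifts:
    shifts: tuple           # signed deg for pairs (1v2, 2v3, 3v4); None if unusable
    usable: tuple           # per-compartment usability flags (4 entries)
    curves: tuple           # per-compartment TuningCurve or None
    mean_shift: float       # circular mean of available shifts, deg


def _pick_shift(angles: np.ndarray, profile: np.ndarray, tol: float = 1e-12) -> float:
    """Argmax with ties broken toward smallest |shift|, then positive sign."""
    finite = np.isfinite(profile)
    if not finite.any():
        raise ValueError("degenerate profile: no finite correlations")
    best = np.nanmax(profile[finite])
    cand = wrap180(angles[finite & (profile >= best - tol)])
    order = np.lexsort((-np.sign(cand), np.abs(cand)))
    return float(cand[order[0]])


def tuning_shift(tc_a: TuningCurve, tc_b: TuningCurve) -> RotationResult:
    """Angle of head-direction shift between two tuning curves.

    Curve a is circularly shifted in 1-bin (1°) increments against curve b;
    the shift maximizing the Pearson correlation is the estimate. The full
    profile is computed with a circular FFT cross-correlation, which is
    exact for full-overlap circular lags.
    """
    a, b = tc_a.rates.astype(float), tc_b.rates.astype(float)
    if len(a) != len(b):
        raise ValueError("tuning curves must share binning")
    n = len(a)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("degenerate curve: constant rates, correlation undefined")
    a0, b0 = a - a.mean(), b - b.mean()
    # profile[s] = corr(roll(a, s), b); roll(a, s)[i] = a[i - s]
    cross = np.fft.irfft(np.conj(np.fft.rfft(a0)) * np.fft.rfft(b0), n=n)
    profile = cross / (n * sa * sb)
    angles = np.arange(n) * tc_a.bin_width
    shift = _pick_shift(angles, profile)
    return RotationResult(shift=shift, max_corr=float(profile.max()),
                          min_corr=float(profile.min()), profile=profile,
                          angles=angles, n_overlap=n)


def _rotate_xy(x, y, center, angle_deg):
    rad = np.deg2rad(angle_deg)
    dx, dy = x - center[0], y - center[1]
    return (center[0] + dx * np.cos(rad) - dy * np.sin(rad),
            center[1] + dx * np.sin(rad) + dy * np.cos(rad))


def map_rotation_shift(session_a: SessionRecording, session_b: SessionRecording,
                       unit_id: str, increment: float = 5.0,
                       bin_size: float = 2.5, smooth_sd: float = 5.0,
                       min_occ: float = 0.1, min_overlap: int = 20,
                       sample_mask_a: Optional[np.ndarray] = None,
                       sample_mask_b: Optional[np.ndarray] = None) -> RotationResult:
    """Angle of place-field rotation between two sessions of one unit.

    Session a's raw samples (positions and spike positions) are rotated
    about the arena center in `increment`-degree steps and re-binned; at
    each angle the Pearson correlation with session b's map is taken over
    bins valid in both maps (rotate-then-bin avoids raster interpolation).
    """
    center = session_a.geometry.center
    # common bounds so bin grids align at every rotation
    minx, miny, maxx, maxy = session_a.geometry.outline.bounds
    cx, cy = center
    half = max(maxx - cx, cx - minx, maxy - cy, cy - miny) + bin_size
    bounds = (cx - half, cy - half, cx + half, cy + half)

    unit_b = session_b.unit(unit_id)
    raw_b, _, valid_b, _, _ = _bin_session(session_b, unit_b, bin_size, min_occ,
                                           sample_mask_b, bounds=bounds)
    map_b = _nan_smooth(raw_b, valid_b, smooth_sd / bin_size)

    unit_a = session_a.unit(unit_id)
    traj_a = session_a.trajectory
    angles = np.arange(0.0, 360.0, increment)
    profile = np.empty(len(angles))
    overlaps = np.empty(len(angles), dtype=int)
    for k, ang in enumerate(angles):
        rx, ry = _rotate_xy(traj_a.x, traj_a.y, center, ang)
        raw_a, _, valid_a, _, _ = _bin_session(session_a, unit_a, bin_size, min_occ,
                                               sample_mask_a, x=rx, y=ry, bounds=bounds)
        map_a = _nan_smooth(raw_a, valid_a, smooth_sd / bin_size)
        both = valid_a & valid_b
        overlaps[k] = int(both.sum())
        if overlaps[k] < min_overlap:
            raise ValueError(
                f"insufficient overlap at {ang:.0f} deg: {overlaps[k]} bins < {min_overlap}")
        va, vb = map_a[both], map_b[both]
        if va.std() == 0 or vb.std() == 0:
            profile[k] = 0.0
        else:
            profile[k] = float(np.corrcoef(va, vb)[0, 1])
    shift = _pick_shift(angles, profile)
    return RotationResult(shift=shift, max_corr=float(np.nanmax(profile)),
                          min_corr=float(np.nanmin(profile)), profile=profile,
                          angles=angles, n_overlap=int(overlaps.min()))


def compartment_tuning_curves(session: SessionRecording, unit_id: str,
                              geometry: Optional[ArenaGeometry] = None,
                              min_spikes: int = 50, min_coverage_deg: float = 180.0,
                              **tc_kwargs):
    """Per-compartment tuning curves for a maze session.

    The sample mask restricts occupancy and spikes to each
    ``compartment_i`` polygon (corridor excluded). A compartment is flagged
    unusable when it holds fewer than `min_spikes` spikes or samples less
    than `min_coverage_deg` of heading (1° bins with any occupancy).
    Returns (curves, usable): lists of 4, curves None where unusable.
    """
    geom = geometry or session.geometry
    names = [f"compartment_{i}" for i in range(1, 5)]
    missing = [nm for nm in names if nm not in geom.regions]
    if missing:
        raise ValueError(f"geometry lacks regions: {missing}")
    unit = session.unit(unit_id)
    traj = session.trajectory
    curves, usable = [], []
    for nm in names:
        mask = shapely.contains_xy(geom.regions[nm], traj.x, traj.y)
        if not mask.any():
            curves.append(None)
            usable.append(False)
            continue
        try:
            tc = tuning_curve(session, unit, sample_mask=mask, **tc_kwargs)
        except ValueError:  # not enough directional sampling in this compartment
            curves.append(None)
            usable.append(False)
            continue
        coverage = float(np.sum(tc.occupancy > 0) * tc.bin_width)
        ok = tc.n_spikes >= min_spikes and coverage >= min_coverage_deg
        curves.append(tc)
        usable.append(ok)
    if not any(usable):
        raise ValueError("no usable compartments for this unit")
    return curves, usable


def adjacent_compartment_shifts(curves, usable=None) -> CompartmentShifts:
    """Tuning shifts between adjacent compartment pairs (1v2, 2v3, 3v4) and
    their circular mean."""
    if usable is None:
        usable = [c is not None for c in curves]
    shifts = []
    for i in range(3):
        if usable[i] and usable[i + 1]:
            try:
                shifts.append(tuning_shift(curves[i], curves[i + 1]).shift)
            except ValueError:
                shifts.append(None)
        else:
            shifts.append(None)
    avail = [s for s in shifts if s is not None]
    if len(avail) < 1:
        raise ValueError("need at least one usable adjacent pair")
    mean = circmean_deg(avail)
    return CompartmentShifts(shifts=tuple(shifts), usable=tuple(usable),
                             curves=tuple(curves), mean_shift=float(wrap180(mean)))


def classify_field_barrier_relation(rm: RateMap, geometry: ArenaGeometry,
                                    adjacency_dist: float = 10.0) -> str:
    """'adjacent' if the field's peak bin center lies within
    `adjacency_dist` cm of the barrier segment (inclusive), else 'distant'."""
    if geometry.barrier is None:
        raise ValueError("no barrier in geometry")
    i, j = rm.peak_bin()
    px, py = rm.bin_center(i, j)
    d = geometry.barrier.distance(Point(px, py))
    return "adjacent" if d <= adjacency_dist else "distant"


def classify_rotation_response(observed_shift: float, commanded_rotation: float,
                               window: float = 30.0) -> str:
    """Classify a shift relative to a commanded landmark rotation.

    'rotated' if within ±window of the commanded rotation (inclusive),
    'unchanged' if within window of zero (exclusive), else 'other'. The two
    windows must not overlap (they cannot for 90° rotations).
    """
    if not (np.isfinite(observed_shift) and np.isfinite(commanded_rotation)):
        raise ValueError("angles must be finite")
    if circdist(commanded_rotation, 0.0) < 2 * window:
        raise ValueError("rotated/unchanged windows overlap for this rotation")
    if circdist(observed_shift, commanded_rotation) <= window:
        return "rotated"
    if circdist(observed_shift, 0.0) < window:
        return "unchanged"
    return "other"


def normalize_shift_sign(shift: float, commanded_rotation: float) -> float:
    """Express a shift relative to the commanded rotation's direction, so
    +90° always means 'with the cue' regardless of whether the landmark was
    rotated clockwise or anticlockwise."""
    if commanded_rotation < 0:
        return float(wrap180(-shift))
    return float(wrap180(shift))
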