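"""Synthetic arenas, foraging trajectories, and spatially tuned spike trains.

The generator stands in for the recordings the analyses were designed for:
a rat foraging in a 100 cm octagon (optionally with a central barrier or a
wall cue card) or in four-compartment parallel/radial mazes, with
head-direction cells firing as unimodal von Mises-shaped functions of
heading and place cells as isotropic Gaussian fields, both spiking as
inhomogeneous Poisson processes. Cue manipulations rotate the underlying
tuning by a commanded angle times a control gain, plus angular noise, which
is exactly the phenomenology (full rotation, under-rotation, failure) the
rotation analyses must recover.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely import affinity

from ._angles import wrap360
from .session import ArenaGeometry, SpikeTrain, Trajectory

__all__ = [
    "HDCellParams",
    "PlaceCellParams",
    "CueManipulation",
    "MotionParams",
    "build_geometry",
    "simulate_trajectory",
    "simulate_hd_cell",
    "simulate_place_cell",
    "apply_manipulation",
]

# paper apparatus dimensions (cm)
OCTAGON_DIAMETER = 100.0          # max width, vertex to vertex
COMPARTMENT_LENGTH = 40.5         # long axis
COMPARTMENT_WIDTH = 35.5
CORRIDOR_WIDTH = 20.0
BARRIER_LENGTH = 70.0
RADIAL_ANGLE = 60.0               # offset between adjacent radial compartments

#: sd (deg) of head direction around movement direction
HEADING_JITTER_SD = 10.0


@dataclass(frozen=True)
class HDCellParams:
    """Unimodal head-direction tuning: rate(θ) = baseline +
    (peak − baseline)·exp(κ_t·(cos(θ − pfd) − 1))."""
    pfd: float                 # preferred firing direction, deg
    kappa_tuning: float = 4.0  # von Mises concentration of the rate function
    peak_rate: float = 30.0    # Hz
    baseline_rate: float = 0.5 # Hz

    def __post_init__(self):
        if self.kappa_tuning < 0:
            raise ValueError("kappa_tuning must be >= 0")
        if not 0 <= self.baseline_rate <= self.peak_rate:
            raise ValueError("need 0 <= baseline_rate <= peak_rate")


@dataclass(frozen=True)
class PlaceCellParams:
    """Single isotropic Gaussian place field."""
    center: tuple[float, float]  # cm
    sigma_field: float = 8.0     # cm
    peak_rate: float = 15.0      # Hz
    baseline_rate: float = 0.05  # Hz

    def __post_init__(self):
        if self.sigma_field <= 0:
            raise ValueError("sigma_field must be > 0")
        if not 0 <= self.baseline_rate <= self.peak_rate:
            raise ValueError("need 0 <= baseline_rate <= peak_rate")


@dataclass(frozen=True)
class CueManipulation:
    """A landmark rotation and how much of it the cell's reference follows.

    control_gain 1 = full stimulus control, 0 = complete failure;
    intermediate values generate the under-rotation seen with weakly
    controlling landmarks. angular_noise_sd adds per-cell wrapped-Gaussian
    scatter on top.
    """
    rotation: float              # deg applied to the landmark
    control_gain: float = 1.0    # in [0, 1]
    angular_noise_sd: float = 0.0  # deg

    def __post_init__(self):
        if not 0 <= self.control_gain <= 1:
            raise ValueError("control_gain must be in [0, 1]")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")


@dataclass(frozen=True)
class MotionParams:
    mean_speed: float = 15.0          # cm/s
    heading_persistence: float = 0.8  # in [0, 1); 1 = straight-line
    turn_sd: float = 60.0             # deg per step before (1 - persistence) scaling
    speed_jitter: float = 0.3         # fractional sd of per-step speed


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def _regular_octagon(diameter: float) -> Polygon:
    radius = diameter / 2.0
    ang = np.deg2rad(np.arange(8) * 45.0 + 22.5)
    return Polygon(np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]))


def _rect(cx, cy, width, length, angle_deg) -> Polygon:
    """Rectangle centered at (cx, cy); long axis (length) along angle_deg."""
    hw, hl = width / 2.0, length / 2.0
    base = Polygon([(-hl, -hw), (hl, -hw), (hl, hw), (-hl, hw)])
    return affinity.translate(affinity.rotate(base, angle_deg, origin=(0, 0)), cx, cy)


def build_geometry(kind: str, **params) -> ArenaGeometry:
    """Construct one of the study arenas.

    kind: 'octagon' (100 cm regular octagon), 'parallel4' / 'radial4'
    (four 40.5 x 35.5 cm compartments off a 20 cm corridor, radial
    compartments at 60° to one another), or 'octagon_barrier' (octagon
    plus a 70 cm central barrier).
    """
    if kind == "octagon":
        return ArenaGeometry(outline=_regular_octagon(params.get("diameter", OCTAGON_DIAMETER)),
                             cue_angle=params.get("cue_angle"))

    if kind == "octagon_barrier":
        outline = _regular_octagon(params.get("diameter", OCTAGON_DIAMETER))
        angle = params.get("barrier_angle", 90.0)
        half = params.get("barrier_length", BARRIER_LENGTH) / 2.0
        dx, dy = math.cos(math.radians(angle)), math.sin(math.radians(angle))
        barrier = LineString([(-half * dx, -half * dy), (half * dx, half * dy)])
        return ArenaGeometry(outline=outline, barrier=barrier,
                             cue_angle=params.get("cue_angle"))

    if kind == "parallel4":
        # corridor along x; compartments side by side below it, long axes +y
        n = 4
        total = n * COMPARTMENT_WIDTH
        corridor = Polygon([(-total / 2, 0), (total / 2, 0),
                            (total / 2, CORRIDOR_WIDTH), (-total / 2, CORRIDOR_WIDTH)])
        regions = {"corridor": corridor}
        for i in range(n):
            cx = -total / 2 + (i + 0.5) * COMPARTMENT_WIDTH
            regions[f"compartment_{i + 1}"] = _rect(
                cx, -COMPARTMENT_LENGTH / 2, COMPARTMENT_WIDTH, COMPARTMENT_LENGTH, 90.0)
        outline = Polygon(shapely.unary_union(list(regions.values())).exterior)
        return ArenaGeometry(outline=outline, regions=regions)

    if kind == "radial4":
        # inverted-U corridor: annulus sector; compartments radiate outward,
        # adjacent long axes 60 deg apart. Rectangles are sunk 3 cm into the
        # corridor for a doorway, then the corridor is subtracted so regions
        # stay pairwise disjoint.
        r_in = 25.0
        r_out = r_in + CORRIDOR_WIDTH
        spoke = np.array([0.0, 60.0, 120.0, 180.0])  # compartment axis directions
        pad = 12.0  # angular padding so the corridor reaches every doorway
        theta = np.deg2rad(np.linspace(spoke.min() - pad, spoke.max() + pad, 80))
        ring = np.concatenate([
            np.column_stack([r_out * np.cos(theta), r_out * np.sin(theta)]),
            np.column_stack([r_in * np.cos(theta[::-1]), r_in * np.sin(theta[::-1])]),
        ])
        corridor = Polygon(ring)
        regions = {"corridor": corridor}
        rects = []
        for i, ang in enumerate(spoke):
            radial_pos = r_out + COMPARTMENT_LENGTH / 2 - 3.0
            cx = radial_pos * math.cos(math.radians(ang))
            cy = radial_pos * math.sin(math.radians(ang))
            rect = _rect(cx, cy, COMPARTMENT_WIDTH, COMPARTMENT_LENGTH, ang)
            rects.append(rect)
            regions[f"compartment_{i + 1}"] = rect.difference(corridor)
        outline = Polygon(shapely.unary_union(rects + [corridor]).buffer(0.01).exterior)
        return ArenaGeometry(outline=outline, regions=regions)

    raise ValueError(f"unknown arena kind {kind!r}")


def compartment_axis_angles(kind: str) -> np.ndarray:
    """Long-axis direction (deg) of compartments 1..4 for a maze kind."""
    if kind == "parallel4":
        return np.array([90.0, 90.0, 90.0, 90.0])
    if kind == "radial4":
        return np.array([0.0, 60.0, 120.0, 180.0])
    raise ValueError(f"no compartments for kind {kind!r}")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

class _FreeSpaceGrid:
    """1 cm boolean lookup of positions safely inside the walkable area."""

    def __init__(self, free: Polygon, margin: float = 1.0, res: float = 1.0):
        self.res = res
        safe = free.buffer(-margin)
        if safe.is_empty:
            raise ValueError("geometry has zero free area at this wall margin")
        minx, miny, maxx, maxy = free.bounds
        self.x0, self.y0 = minx - 2 * res, miny - 2 * res
        nx = int(np.ceil((maxx - self.x0) / res)) + 4
        ny = int(np.ceil((maxy - self.y0) / res)) + 4
        gx = self.x0 + (np.arange(nx) + 0.5) * res
        gy = self.y0 + (np.arange(ny) + 0.5) * res
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        # conservative: cell centers inside an extra half-diagonal shrink
        inner = safe.buffer(-res * 0.75)
        if inner.is_empty:
            inner = safe
        self.mask = shapely.contains_xy(inner, xx.ravel(), yy.ravel()).reshape(nx, ny)
        if not self.mask.any():
            raise ValueError("geometry has zero free area")
        free_idx = np.argwhere(self.mask)
        self._free_centers = np.column_stack([
            self.x0 + (free_idx[:, 0] + 0.5) * res,
            self.y0 + (free_idx[:, 1] + 0.5) * res])

    def inside(self, x: float, y: float) -> bool:
        i = int((x - self.x0) / self.res)
        j = int((y - self.y0) / self.res)
        if 0 <= i < self.mask.shape[0] and 0 <= j < self.mask.shape[1]:
            return bool(self.mask[i, j])
        return False

    def random_start(self, rng: np.random.Generator) -> tuple[float, float]:
        c = self._free_centers[rng.integers(len(self._free_centers))]
        return float(c[0]), float(c[1])


def simulate_trajectory(geom: ArenaGeometry, duration: float = 1200.0,
                        motion: MotionParams = MotionParams(),
                        seed: int | np.random.SeedSequence = 0,
                        dt: float = 0.02) -> Trajectory:
    """Correlated random walk confined to the arena's free space.

    Movement direction evolves by wrapped-Gaussian increments of sd
    ``(1 - heading_persistence) * turn_sd`` per step; per-step speed is
    mean_speed with truncated-Gaussian jitter; wall collisions reverse the
    movement direction (with scatter) without advancing. Head direction is
    movement direction plus 10° sd wrapped-Gaussian jitter.
    """
    if duration < 60:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng(seed)
    grid = _FreeSpaceGrid(geom.free_space)
    n = int(round(duration / dt))
    turn_sd = (1.0 - motion.heading_persistence) * motion.turn_sd

    turns = rng.normal(0.0, turn_sd, size=n)
    speeds = rng.normal(motion.mean_speed, motion.speed_jitter * motion.mean_speed, size=n)
    np.clip(speeds, 0.0, None, out=speeds)
    bounce = rng.normal(180.0, 30.0, size=n)
    hd_jitter = rng.normal(0.0, HEADING_JITTER_SD, size=n)

    x = np.empty(n)
    y = np.empty(n)
    move_dir = np.empty(n)
    cx, cy = grid.random_start(rng)
    d = rng.uniform(0.0, 360.0)
    for i in range(n):
        d = (d + turns[i]) % 360.0
        step = speeds[i] * dt
        rad = math.radians(d)
        nx_, ny_ = cx + step * math.cos(rad), cy + step * math.sin(rad)
        if not grid.inside(nx_, ny_):
            d = (d + bounce[i]) % 360.0
            rad = math.radians(d)
            nx_, ny_ = cx + step * math.cos(rad), cy + step * math.sin(rad)
            if not grid.inside(nx_, ny_):
                nx_, ny_ = cx, cy  # stay put this frame
        cx, cy = nx_, ny_
        x[i], y[i], move_dir[i] = cx, cy, d

    heading = wrap360(move_dir + hd_jitter)
    times = np.arange(n) * dt
    return Trajectory(times=times, x=x, y=y, heading=heading)


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------

def _poisson_spikes_from_rate(rate_hz: np.ndarray, times: np.ndarray, dt: float,
                              rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(rate_hz * dt)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(times, counts)
    spikes = np.sort(starts + rng.uniform(0.0, dt, size=total))
    # the last frame extends dt past the final timestamp; keep spikes inside
    # the tracked time range
    return np.minimum(spikes, times[-1])


def hd_rate(heading_deg: np.ndarray, p: HDCellParams) -> np.ndarray:
    """Instantaneous firing rate (Hz) of an HD cell at given headings."""
    delta = np.deg2rad(np.asarray(heading_deg, dtype=float) - p.pfd)
    return p.baseline_rate + (p.peak_rate - p.baseline_rate) * np.exp(
        p.kappa_tuning * (np.cos(delta) - 1.0))


def place_rate(x: np.ndarray, y: np.ndarray, p: PlaceCellParams) -> np.ndarray:
    """Instantaneous firing rate (Hz) of a place cell at given positions."""
    d2 = (np.asarray(x, float) - p.center[0]) ** 2 + (np.asarray(y, float) - p.center[1]) ** 2
    return p.baseline_rate + (p.peak_rate - p.baseline_rate) * np.exp(
        -d2 / (2.0 * p.sigma_field ** 2))


def simulate_hd_cell(traj: Trajectory, p: HDCellParams,
                     seed: int | np.random.SeedSequence = 0,
                     unit_id: str = "hd", session_id: str = "") -> SpikeTrain:
    """Inhomogeneous-Poisson spikes driven by the cell's directional tuning
    evaluated on the trajectory's head-direction channel."""
    rng = np.random.default_rng(seed)
    rate = hd_rate(traj.heading, p)
    st = _poisson_spikes_from_rate(rate, traj.times, traj.dt, rng)
    return SpikeTrain(st, unit_id=unit_id, session_id=session_id)


def simulate_place_cell(traj: Trajectory, p: PlaceCellParams,
                        seed: int | np.random.SeedSequence = 0,
                        unit_id: str = "place", session_id: str = "",
                        spike_width: float = 0.35) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes driven by a Gaussian place field."""
    rng = np.random.default_rng(seed)
    rate = place_rate(traj.x, traj.y, p)
    st = _poisson_spikes_from_rate(rate, traj.times, traj.dt, rng)
    return SpikeTrain(st, unit_id=unit_id, session_id=session_id, spike_width=spike_width)


def simulate_hd_cell_by_region(traj: Trajectory, geom: ArenaGeometry,
                               pfd_by_region: dict[str, float], p: HDCellParams,
                               seed: int | np.random.SeedSequence = 0,
                               unit_id: str = "hd", session_id: str = "") -> SpikeTrain:
    """HD cell whose preferred direction re-anchors per named region — the
    'local reference' hypothesis. Samples in regions not listed keep p.pfd."""
    rng = np.random.default_rng(seed)
    pfd = np.full(len(traj), p.pfd)
    for name, value in pfd_by_region.items():
        if name not in geom.regions:
            raise KeyError(f"region {name!r} not in geometry")
        m = shapely.contains_xy(geom.regions[name], traj.x, traj.y)
        pfd[m] = value
    delta = np.deg2rad(traj.heading - pfd)
    rate = p.baseline_rate + (p.peak_rate - p.baseline_rate) * np.exp(
        p.kappa_tuning * (np.cos(delta) - 1.0))
    st = _poisson_spikes_from_rate(rate, traj.times, traj.dt, rng)
    return SpikeTrain(st, unit_id=unit_id, session_id=session_id)


# ---------------------------------------------------------------------------
# cue manipulation
# ---------------------------------------------------------------------------

def apply_manipulation(p, m: CueManipulation, geom_center=(0.0, 0.0),
                       seed: int | np.random.SeedSequence = 0):
    """Rotate a cell's tuning reference in response to a landmark rotation.

    The effective rotation is δ = rotation·control_gain + N(0, noise_sd),
    wrapped. HD cells shift their preferred direction by δ; place-field
    centers rotate by δ about the arena center. Returns (new_params, δ)
    with δ in (-180, 180].
    """
    rng = np.random.default_rng(seed)
    delta = m.rotation * m.control_gain
    if m.angular_noise_sd > 0:
        delta += rng.normal(0.0, m.angular_noise_sd)
    delta = float((delta + 180.0) % 360.0 - 180.0)
    if delta == -180.0:
        delta = 180.0
    if isinstance(p, HDCellParams):
        return replace(p, pfd=float(wrap360(p.pfd + delta))), delta
    if isinstance(p, PlaceCellParams):
        rad = math.radians(delta)
        dx = p.center[0] - geom_center[0]
        dy = p.center[1] - geom_center[1]
        new = (geom_center[0] + dx * math.cos(rad) - dy * math.sin(rad),
               geom_center[1] + dx * math.sin(rad) + dy * math.cos(rad))
        return replace(p, center=new), delta
    raise TypeError(f"unsupported parameter type {type(p).__name__}")
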