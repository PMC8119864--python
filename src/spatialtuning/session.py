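"""Session data model, file I/O, and kinematic preprocessing.

A recording session couples a tracked foraging trajectory (time, position,
head direction) with the spike trains of simultaneously recorded units and
a description of the arena geometry. All positions are in cm in an
arena-centered frame (y up); head direction is in degrees, [0, 360),
counterclockwise from +x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from ._angles import wrap360

__all__ = [
    "SessionValidationError",
    "Trajectory",
    "SpikeTrain",
    "ArenaGeometry",
    "SessionRecording",
    "load_session",
    "write_session",
    "compute_speed",
    "speed_filter",
    "spike_sample_indices",
]

#: how far (cm) a tracked position may sit outside the arena outline before
#: validation rejects it; absorbs tracking jitter at the walls.
WALL_TOLERANCE_CM = 1.0


class SessionValidationError(ValueError):
    """Validation failure naming the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled position + head-direction time series.

    times are seconds, strictly increasing with constant step dt; x, y in
    cm (arena-centered); heading in degrees [0, 360).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        for name in ("times", "x", "y", "heading"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if n < 2:
            raise SessionValidationError("times", "trajectory needs at least 2 samples")
        for name in ("x", "y", "heading"):
            if len(getattr(self, name)) != n:
                raise SessionValidationError(name, "length differs from times")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise SessionValidationError("times", "time must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise SessionValidationError("times", "sampling step must be uniform (within 1e-9 s)")
        object.__setattr__(self, "heading", wrap360(self.heading))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total sampled time in seconds (n_samples * dt)."""
        return len(self.times) * self.dt

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) of one unit in one session."""

    spike_times: np.ndarray
    session_id: str = ""
    unit_id: str = ""
    spike_width: Optional[float] = None  # ms, used by the place-cell criterion

    def __post_init__(self):
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise SessionValidationError("spike_times", "must be one-dimensional")
        if len(st) and np.any(np.diff(st) < 0):
            raise SessionValidationError("spike_times", "must be sorted")
        if len(st) and st[0] < 0:
            raise SessionValidationError("spike_times", "must be non-negative")
        object.__setattr__(self, "spike_times", st)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena outline plus named sub-regions, all in cm.

    regions maps names (e.g. ``compartment_1`` .. ``compartment_4``,
    ``corridor``) to polygons; barrier, if present, is a 2-point line
    segment; cue_angle is the angular position (deg) of the cue-card
    midpoint on the wall.
    """

    outline: Polygon
    center: tuple[float, float] = (0.0, 0.0)
    regions: dict[str, Polygon] = field(default_factory=dict)
    barrier: Optional[LineString] = None
    cue_angle: Optional[float] = None

    def __post_init__(self):
        if not self.outline.is_valid or self.outline.area <= 0:
            raise SessionValidationError("outline", "must be a valid polygon of positive area")
        grown = self.outline.buffer(1e-6)
        for name, poly in self.regions.items():
            if not grown.contains(poly):
                raise SessionValidationError("regions", f"region {name!r} not contained in outline")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.regions[a].intersection(self.regions[b])
                if inter.area > 1e-6:
                    raise SessionValidationError("regions", f"regions {a!r} and {b!r} overlap")
        if self.barrier is not None and not grown.contains(self.barrier):
            raise SessionValidationError("barrier", "barrier must lie inside outline")

    @property
    def free_space(self) -> Polygon:
        """Polygon the animal can occupy: the union of named regions if any,
        else the outline, minus a thin exclusion strip around the barrier."""
        if self.regions:
            free = shapely.unary_union(list(self.regions.values()))
        else:
            free = self.outline
        if self.barrier is not None:
            free = free.difference(self.barrier.buffer(1.0))
        return free


@dataclass(frozen=True)
class SessionRecording:
    """One session: trajectory + spike trains + geometry + condition label."""

    trajectory: Trajectory
    spikes: list[SpikeTrain]
    geometry: ArenaGeometry
    condition_label: str = "standard"
    session_id: str = ""

    def __post_init__(self):
        t_end = self.trajectory.times[-1]
        for st in self.spikes:
            if st.n_spikes and st.spike_times[-1] > t_end + 1e-9:
                raise SessionValidationError(
                    "spike_times", f"spike outside session (unit {st.unit_id!r}, "
                    f"t={st.spike_times[-1]:.3f} > {t_end:.3f})")
        inside = shapely.contains_xy(
            self.geometry.outline.buffer(WALL_TOLERANCE_CM),
            self.trajectory.x, self.trajectory.y)
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            raise SessionValidationError(
                "x,y", f"position outside arena at sample {i} "
                f"({self.trajectory.x[i]:.1f}, {self.trajectory.y[i]:.1f})")

    def unit(self, unit_id: str) -> SpikeTrain:
        for st in self.spikes:
            if st.unit_id == unit_id:
                return st
        raise KeyError(f"unit {unit_id!r} not in session {self.session_id!r}")

    @property
    def duration(self) -> float:
        return self.trajectory.duration


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _geometry_from_dict(d: dict) -> ArenaGeometry:
    try:
        outline = Polygon([(float(x), float(y)) for x, y in d["outline"]])
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionValidationError("outline", f"malformed geometry outline: {exc}") from None
    center = tuple(d.get("center", (0.0, 0.0)))
    regions = {name: Polygon(pts) for name, pts in d.get("regions", {}).items()}
    barrier = None
    if d.get("barrier") is not None:
        pts = d["barrier"]
        if len(pts) != 2:
            raise SessionValidationError("barrier", "barrier needs exactly two endpoints")
        barrier = LineString(pts)
    cue = d.get("cue_angle_deg")
    return ArenaGeometry(outline=outline, center=(float(center[0]), float(center[1])),
                         regions=regions, barrier=barrier,
                         cue_angle=None if cue is None else float(cue))


def _geometry_to_dict(geom: ArenaGeometry) -> dict:
    d: dict = {
        "outline": [[round(x, 6), round(y, 6)] for x, y in geom.outline.exterior.coords[:-1]],
        "center": [geom.center[0], geom.center[1]],
        "regions": {name: [[round(x, 6), round(y, 6)] for x, y in poly.exterior.coords[:-1]]
                    for name, poly in geom.regions.items()},
    }
    if geom.barrier is not None:
        d["barrier"] = [list(c) for c in geom.barrier.coords]
    if geom.cue_angle is not None:
        d["cue_angle_deg"] = geom.cue_angle
    return d


def load_geometry(path) -> ArenaGeometry:
    with open(path) as fh:
        return _geometry_from_dict(json.load(fh))


def load_session(tracking_path, spike_paths: Sequence, geometry_path,
                 condition_label: str = "standard", session_id: str = "") -> SessionRecording:
    """Read a session from a tracking CSV (t,x,y,hd), per-unit spike CSVs
    (single column t), and a JSON geometry file.

    Heading values are wrapped into [0, 360). Raises
    :class:`SessionValidationError` naming the offending field on any
    malformed input.
    """
    df = pd.read_csv(tracking_path)
    for col in ("t", "x", "y", "hd"):
        if col not in df.columns:
            raise SessionValidationError(col, f"missing column in {tracking_path}")
    traj = Trajectory(df["t"].to_numpy(), df["x"].to_numpy(),
                      df["y"].to_numpy(), df["hd"].to_numpy())
    geom = load_geometry(geometry_path)
    spikes = []
    for p in spike_paths:
        sdf = pd.read_csv(p)
        if "t" not in sdf.columns:
            raise SessionValidationError("t", f"missing column in spike file {p}")
        width = float(sdf["width_ms"].iloc[0]) if "width_ms" in sdf.columns and len(sdf) else None
        spikes.append(SpikeTrain(np.sort(sdf["t"].to_numpy(dtype=float)),
                                 session_id=session_id, unit_id=Path(p).stem,
                                 spike_width=width))
    return SessionRecording(trajectory=traj, spikes=spikes, geometry=geom,
                            condition_label=condition_label, session_id=session_id)


def write_session(session: SessionRecording, out_dir) -> dict[str, Path]:
    """Write tracking.csv, geometry.json, and one spikes CSV per unit.

    Numeric content survives a write/load round trip to 6 decimals.
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tr = session.trajectory
    track = out / "tracking.csv"
    pd.DataFrame({"t": tr.times, "x": tr.x, "y": tr.y, "hd": tr.heading}).to_csv(
        track, index=False, float_format="%.6f")
    paths["tracking"] = track
    geo = out / "geometry.json"
    geo.write_text(json.dumps(_geometry_to_dict(session.geometry), indent=1))
    paths["geometry"] = geo
    for st in session.spikes:
        p = out / f"{st.unit_id or 'unit'}.csv"
        df = pd.DataFrame({"t": st.spike_times})
        if st.spike_width is not None:
            df["width_ms"] = st.spike_width
        df.to_csv(p, index=False, float_format="%.6f")
        paths[f"spikes:{st.unit_id}"] = p
    return paths


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def compute_speed(traj: Trajectory) -> np.ndarray:
    """Running speed (cm/s) by centered finite differences of position;
    one-sided at the endpoints. Same length as the trajectory."""
    n = len(traj)
    vx = np.gradient(traj.x, traj.times)
    vy = np.gradient(traj.y, traj.times)
    speed = np.hypot(vx, vy)
    assert len(speed) == n
    return speed


def spike_sample_indices(traj: Trajectory, spike_times: np.ndarray) -> np.ndarray:
    """Index of the trajectory sample nearest in time to each spike
    (ties broken toward the earlier sample)."""
    t = traj.times
    idx = np.searchsorted(t, spike_times)
    idx = np.clip(idx, 1, len(t) - 1)
    left_closer = (spike_times - t[idx - 1]) <= (t[idx] - spike_times)
    return np.where(left_closer, idx - 1, idx)


def speed_filter(session: SessionRecording, unit: SpikeTrain,
                 threshold: float = 3.0) -> tuple[SpikeTrain, np.ndarray]:
    """Drop spikes emitted while the animal moved at or below `threshold`
    cm/s (paper protocol: keep only >3 cm/s movement).

    Returns the filtered train and the boolean mask of retained trajectory
    samples, so occupancy can be filtered identically.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    speed = compute_speed(session.trajectory)
    mask = speed > threshold
    if unit.n_spikes == 0:
        return unit, mask
    idx = spike_sample_indices(session.trajectory, unit.spike_times)
    keep = mask[idx]
    return replace(unit, spike_times=unit.spike_times[keep]), mask
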