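"""Cell-type inclusion criteria.

A unit counts as a head-direction cell when its directional tuning (mean
vector length r >= 0.2) and mean rate (>= 0.3 Hz) clear threshold in both
open-field sessions bracketing the maze sessions; in the cue/barrier
experiment it must additionally fire at least 100 spikes in every session.
A unit counts as a place cell when, in the first session of a rotation
series and after the 3 cm/s speed filter, its spatial information exceeds
0.5 bits/spike, its mean rate lies in [0.15, 6] Hz, and its spike width
exceeds 0.25 ms.

Boundary semantics follow the criteria verbatim: r and rate thresholds are
inclusive (>=), spatial information and spike width strict (>), the rate
band inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .maps import mean_vector, rate_map, spatial_information, tuning_curve
from .session import SessionRecording, SpikeTrain, speed_filter

__all__ = [
    "CriteriaHD",
    "CriteriaPlace",
    "HDClassification",
    "PlaceClassification",
    "classify_hd_cell",
    "classify_place_cell",
]


@dataclass(frozen=True)
class CriteriaHD:
    min_r: float = 0.2
    min_mean_rate: float = 0.3          # Hz
    min_spikes_per_session: int = 100   # enforced only when all_sessions given

    def __post_init__(self):
        if self.min_r <= 0 or self.min_mean_rate <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class CriteriaPlace:
    min_si: float = 0.5                 # bits/spike, strict
    rate_band: tuple[float, float] = (0.15, 6.0)  # Hz, inclusive
    min_spike_width: float = 0.25       # ms, strict
    speed_threshold: float = 3.0        # cm/s

    def __post_init__(self):
        if self.rate_band[0] >= self.rate_band[1]:
            raise ValueError("rate band lower bound must be below upper bound")


@dataclass(frozen=True)
class HDClassification:
    accepted: bool
    r_values: tuple[float, float]
    mean_rates: tuple[float, float]
    spike_counts: tuple[int, ...] = ()
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlaceClassification:
    accepted: bool
    spatial_information: float
    mean_rate: float
    spike_width: Optional[float]
    reasons: tuple[str, ...] = ()


def hd_metrics_pass(r_values, mean_rates, c: CriteriaHD,
                    spike_counts: Sequence[int] = ()) -> tuple[bool, tuple[str, ...]]:
    """Re-apply the HD thresholds to already-computed metrics."""
    reasons = []
    for i, (r, rate) in enumerate(zip(r_values, mean_rates), start=1):
        if not r >= c.min_r:
            reasons.append(f"bracket session {i}: r={r:.3f} < {c.min_r}")
        if not rate >= c.min_mean_rate:
            reasons.append(f"bracket session {i}: mean rate {rate:.3f} Hz < {c.min_mean_rate}")
    for i, n in enumerate(spike_counts, start=1):
        if n < c.min_spikes_per_session:
            reasons.append(f"session {i}: {n} spikes < {c.min_spikes_per_session}")
    return (not reasons), tuple(reasons)


def classify_hd_cell(bracket_sessions: Sequence[SessionRecording], unit_id: str,
                     c: CriteriaHD = CriteriaHD(),
                     all_sessions: Optional[Sequence[SessionRecording]] = None,
                     ) -> HDClassification:
    """Apply the HD-cell criterion to one unit.

    `bracket_sessions` are the two open-field sessions around the maze
    sessions; if `all_sessions` is given (cue/barrier experiment mode), the
    per-session minimum spike count is enforced across all of them. Mean
    rate is spikes over the whole session duration — no speed filter, per
    the HD protocol. All metrics are returned regardless of the decision.
    """
    if len(bracket_sessions) != 2:
        raise ValueError("exactly two bracketing sessions required")
    rs, rates = [], []
    for sess in bracket_sessions:
        unit = sess.unit(unit_id)  # raises KeyError if missing
        stats = mean_vector(tuning_curve(sess, unit))
        rs.append(stats.r if stats.defined else 0.0)
        rates.append(unit.n_spikes / sess.duration)
    counts: tuple[int, ...] = ()
    if all_sessions is not None:
        counts = tuple(sess.unit(unit_id).n_spikes for sess in all_sessions)
    ok, reasons = hd_metrics_pass(rs, rates, c, counts)
    return HDClassification(accepted=ok, r_values=(rs[0], rs[1]),
                            mean_rates=(rates[0], rates[1]),
                            spike_counts=counts, reasons=reasons)


def place_metrics_pass(si, mean_rate, width, c: CriteriaPlace) -> tuple[bool, tuple[str, ...]]:
    """Re-apply the place-cell thresholds to already-computed metrics."""
    reasons = []
    if not si > c.min_si:
        reasons.append(f"SI {si:.3f} bits/spike not > {c.min_si}")
    if not c.rate_band[0] <= mean_rate <= c.rate_band[1]:
        reasons.append(f"mean rate {mean_rate:.3f} Hz outside [{c.rate_band[0]}, {c.rate_band[1]}]")
    if not width > c.min_spike_width:
        reasons.append(f"spike width {width:.3f} ms not > {c.min_spike_width}")
    return (not reasons), tuple(reasons)


def classify_place_cell(first_session: SessionRecording, unit_id: str,
                        c: CriteriaPlace = CriteriaPlace()) -> PlaceClassification:
    """Apply the place-cell criterion to one unit in the first session of a
    rotation series. The speed filter is applied before every metric."""
    unit = first_session.unit(unit_id)
    if unit.spike_width is None:
        raise ValueError(f"unit {unit_id!r} has no spike-width annotation")
    filtered, mask = speed_filter(first_session, unit, c.speed_threshold)
    dt = first_session.trajectory.dt
    filtered_duration = float(mask.sum()) * dt
    mean_rate = filtered.n_spikes / filtered_duration if filtered_duration > 0 else 0.0
    try:
        rm = rate_map(first_session, filtered, sample_mask=mask)
        si = spatial_information(rm)
    except ValueError:
        si = 0.0
    ok, reasons = place_metrics_pass(si, mean_rate, unit.spike_width, c)
    return PlaceClassification(accepted=ok, spatial_information=si,
                               mean_rate=mean_rate, spike_width=unit.spike_width,
                               reasons=reasons)
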