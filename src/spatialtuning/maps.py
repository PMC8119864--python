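"""Occupancy-normalized directional tuning curves and 2D firing-rate maps.

A tuning curve is firing rate versus head direction over 1° circular bins;
a rate map is firing rate versus position over square spatial bins. Both
are occupancy-normalized (spike count divided by time spent), smoothed with
Gaussian kernels, and summarized by the statistics the cell-selection
criteria use: the mean vector length r for directional tuning and the
Skaggs spatial-information index (bits/spike) for spatial tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from ._angles import resultant
from .session import SessionRecording, SpikeTrain, spike_sample_indices

__all__ = [
    "TuningCurve",
    "RateMap",
    "DirectionalStats",
    "tuning_curve",
    "mean_vector",
    "rate_map",
    "spatial_information",
    "write_tuning_curve",
    "write_rate_map",
]


@dataclass(frozen=True)
class TuningCurve:
    """Directional firing-rate curve on a circular bin grid.

    rates are the smoothed occupancy-normalized rates used for tuning
    statistics and cross-correlation; rates_raw are pre-smoothing, on which
    spike-count conservation holds: sum(rates_raw * occupancy) == n_spikes.
    """

    bin_centers: np.ndarray  # deg
    rates: np.ndarray        # Hz, smoothed
    rates_raw: np.ndarray    # Hz, unsmoothed
    occupancy: np.ndarray    # s per bin
    n_spikes: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class RateMap:
    """2D firing-rate map; invalid (unvisited) bins are NaN."""

    bin_size: float          # cm
    origin: tuple[float, float]  # lower-left corner of bin (0, 0)
    rates: np.ndarray        # Hz, smoothed, NaN where invalid; shape (nx, ny)
    rates_raw: np.ndarray    # Hz, unsmoothed, NaN where invalid
    occupancy: np.ndarray    # s
    n_spikes: int

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.rates_raw)

    def bin_center(self, i: int, j: int) -> tuple[float, float]:
        return (self.origin[0] + (i + 0.5) * self.bin_size,
                self.origin[1] + (j + 0.5) * self.bin_size)

    def peak_bin(self) -> tuple[int, int]:
        """Indices of the maximum-rate valid bin (smoothed rates)."""
        r = np.where(self.valid, self.rates, -np.inf)
        return tuple(int(v) for v in np.unravel_index(np.argmax(r), r.shape))


@dataclass(frozen=True)
class DirectionalStats:
    r: float               # mean vector length, [0, 1]; NaN if undefined
    mean_direction: float  # deg; NaN if undefined
    peak_rate: float       # Hz
    mean_rate: float       # Hz
    defined: bool = True


def _circular_fill(rates: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Fill bad bins by circular linear interpolation between the nearest
    good bins on either side."""
    if good.all():
        return rates
    if not good.any():
        raise ValueError("insufficient directional sampling: no bin meets the occupancy floor")
    n = len(rates)
    idx_good = np.flatnonzero(good)
    out = rates.copy()
    for i in np.flatnonzero(~good):
        # nearest good neighbors going down/up (circularly)
        below = idx_good[idx_good < i]
        above = idx_good[idx_good > i]
        lo = below[-1] if len(below) else idx_good[-1] - n
        hi = above[0] if len(above) else idx_good[0] + n
        w = (i - lo) / (hi - lo)
        out[i] = (1 - w) * rates[lo % n] + w * rates[hi % n]
    return out


def tuning_curve(session: SessionRecording, unit: SpikeTrain,
                 bin_width: float = 1.0, smooth_sd: float = 6.0,
                 min_occ: float = 0.1,
                 sample_mask: Optional[np.ndarray] = None) -> TuningCurve:
    """Head-direction tuning curve of one unit.

    Occupancy is time spent per heading bin; the rate is spikes per bin
    divided by occupancy. Bins under the `min_occ` occupancy floor are
    filled by circular interpolation before circular-Gaussian smoothing
    (sd `smooth_sd` degrees). An optional boolean `sample_mask` restricts
    both occupancy and spikes to a subset of trajectory samples (speed
    filter, compartment restriction), keeping the two consistent.
    """
    traj = session.trajectory
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, nbins + 1)
    centers = edges[:-1] + bin_width / 2.0

    heading = traj.heading
    idx = spike_sample_indices(traj, unit.spike_times)
    if sample_mask is not None:
        keep_spike = sample_mask[idx]
        idx = idx[keep_spike]
        heading = heading[sample_mask]
    occupancy = np.histogram(heading, bins=edges)[0] * traj.dt
    spike_hd = traj.heading[idx]
    counts = np.histogram(spike_hd, bins=edges)[0]

    good = occupancy >= min_occ
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1.0), 0.0)
    filled = _circular_fill(raw, good)
    smoothed = gaussian_filter1d(filled, sigma=smooth_sd / bin_width, mode="wrap")
    return TuningCurve(bin_centers=centers, rates=smoothed, rates_raw=raw,
                       occupancy=occupancy, n_spikes=int(counts.sum()))


def mean_vector(tc: TuningCurve) -> DirectionalStats:
    """Rate-weighted mean vector of a tuning curve.

    Weighting by the occupancy-normalized rate (not by spikes) removes
    occupancy bias. mean_rate is total spikes over total time. An all-zero
    curve has no defined direction and is flagged rather than reported as
    r = 0.
    """
    total_occ = tc.occupancy.sum()
    mean_rate = float(np.sum(tc.rates_raw * tc.occupancy) / total_occ) if total_occ > 0 else 0.0
    peak = float(tc.rates.max())
    if tc.rates.sum() <= 0:
        return DirectionalStats(r=float("nan"), mean_direction=float("nan"),
                                peak_rate=peak, mean_rate=mean_rate, defined=False)
    r, mu = resultant(tc.bin_centers, weights=tc.rates)
    return DirectionalStats(r=r, mean_direction=mu, peak_rate=peak, mean_rate=mean_rate)


def _nan_smooth(values: np.ndarray, valid: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing over valid bins only, kernel renormalized over the
    valid support; invalid bins stay NaN."""
    v = np.where(valid, values, 0.0)
    w = valid.astype(float)
    num = gaussian_filter(v, sigma=sigma_bins, mode="constant")
    den = gaussian_filter(w, sigma=sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def _bin_session(session, unit, bin_size, min_occ, sample_mask,
                 x=None, y=None, bounds=None):
    """Shared binning core; x/y override lets callers rotate raw samples."""
    traj = session.trajectory
    if x is None:
        x, y = traj.x, traj.y
    if bounds is None:
        minx, miny, maxx, maxy = session.geometry.outline.bounds
    else:
        minx, miny, maxx, maxy = bounds
    nx = int(np.ceil((maxx - minx) / bin_size))
    ny = int(np.ceil((maxy - miny) / bin_size))
    ex = minx + np.arange(nx + 1) * bin_size
    ey = miny + np.arange(ny + 1) * bin_size

    idx = spike_sample_indices(traj, unit.spike_times)
    if sample_mask is not None:
        idx = idx[sample_mask[idx]]
        xs, ys = x[sample_mask], y[sample_mask]
    else:
        xs, ys = x, y
    occ = np.histogram2d(xs, ys, bins=(ex, ey))[0] * traj.dt
    counts = np.histogram2d(x[idx], y[idx], bins=(ex, ey))[0]
    valid = occ >= min_occ
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = counts / occ
    raw[~valid] = np.nan
    return raw, occ, valid, (minx, miny), int(counts[valid].sum())


def rate_map(session: SessionRecording, unit: SpikeTrain,
             bin_size: float = 2.5, smooth_sd: float = 5.0, min_occ: float = 0.1,
             sample_mask: Optional[np.ndarray] = None,
             min_valid_bins: int = 20) -> RateMap:
    """Positional firing-rate map of one unit.

    Spikes are assigned the position of their nearest trajectory sample.
    Bins with occupancy below `min_occ` seconds (including anything outside
    the arena) are invalid; smoothing (Gaussian, sd `smooth_sd` cm) runs
    over valid bins only with the kernel renormalized on the valid support.
    """
    raw, occ, valid, origin, n_spk = _bin_session(
        session, unit, bin_size, min_occ, sample_mask)
    if valid.sum() < min_valid_bins:
        raise ValueError(
            f"insufficient spatial sampling: {int(valid.sum())} valid bins < {min_valid_bins}")
    smoothed = _nan_smooth(raw, valid, smooth_sd / bin_size)
    return RateMap(bin_size=bin_size, origin=origin, rates=smoothed,
                   rates_raw=raw, occupancy=occ, n_spikes=n_spk)


def spatial_information(rm: RateMap) -> float:
    """Skaggs spatial information index in bits/spike.

    SI = Σ_i p_i (λ_i/λ̄) log2(λ_i/λ̄) over valid bins, with p_i the
    occupancy probability and λ̄ the occupancy-weighted mean rate; computed
    on unsmoothed rates (smoothing deflates information). Zero-rate bins
    contribute 0.
    """
    valid = rm.valid
    occ = rm.occupancy[valid]
    lam = rm.rates_raw[valid]
    p = occ / occ.sum()
    mean_rate = float(np.sum(p * lam))
    if mean_rate <= 0:
        raise ValueError("zero mean rate: spatial information undefined")
    ratio = lam / mean_rate
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tuning_curve(tc: TuningCurve, path) -> None:
    pd.DataFrame({"bin_deg": tc.bin_centers, "rate_hz": tc.rates,
                  "occ_s": tc.occupancy}).to_csv(path, index=False, float_format="%.6f")


def write_rate_map(rm: RateMap, path) -> None:
    """CSV grid of smoothed rates (rows = x bins) plus a sidecar .meta.json."""
    import json
    p = Path(path)
    np.savetxt(p, rm.rates, delimiter=",", fmt="%.6f")
    meta = {"bin_size_cm": rm.bin_size, "origin": list(rm.origin),
            "n_spikes": rm.n_spikes, "shape": list(rm.rates.shape)}
    p.with_suffix(p.suffix + ".meta.json").write_text(json.dumps(meta))
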