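"""End-to-end in-silico experiments.

Two orchestrated pipelines mirror the study designs:

* compartments — a population of simulated HD cells recorded in two
  bracketing octagon sessions plus a parallel and a radial four-compartment
  maze; cells are classified, adjacent-compartment tuning shifts estimated,
  and the global-vs-local reference question answered with the circular
  inference battery (V-test toward 0°, Moore's paired test and a
  concentration comparison between maze configurations).

* cue_barrier — simulated HD cells (three-session series: standard, 90°
  rotation, return) or place cells (two-session series) under a wall cue
  card versus a central barrier, each condition with its own stimulus
  control gain; shifts are estimated by rotational cross-correlation,
  sign-normalized to the commanded rotation, and compared across
  conditions; place-cell responses are additionally classified
  (rotated/unchanged/other) stratified by field-to-barrier adjacency.

Both pipelines are deterministic given the config seed, and every summary
number is recomputable from the emitted per-cell table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point

from ._angles import wrap180, wrap360
from .circstats import TestResult, compare_kappa, moore_paired_test, v_test
from .classify import CriteriaHD, CriteriaPlace, classify_hd_cell, classify_place_cell
from .maps import rate_map
from .rotation import (adjacent_compartment_shifts, classify_field_barrier_relation,
                       classify_rotation_response, compartment_tuning_curves,
                       map_rotation_shift, normalize_shift_sign, tuning_shift)
from .maps import tuning_curve
from .session import SessionRecording, speed_filter
from .synthetic import (CueManipulation, HDCellParams, MotionParams, PlaceCellParams,
                        apply_manipulation, build_geometry, compartment_axis_angles,
                        simulate_hd_cell, simulate_hd_cell_by_region,
                        simulate_place_cell, simulate_trajectory)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_compartment_experiment",
    "run_cue_barrier_experiment",
    "run_experiment",
]

log = logging.getLogger("spatialtuning.pipeline")


@dataclass
class ExperimentConfig:
    """Configuration of one in-silico experiment.

    reference_mode ('global'|'local') selects the hypothesis the simulated
    HD population embodies in the compartment experiment. For cue_barrier,
    cue_gain/barrier_gain set the per-condition stimulus control and
    cell_type picks HD (three sessions) or place (two sessions) series;
    barrier_adjacent_gain/barrier_distant_gain, if set, override the
    barrier gain by the field's true proximity to the barrier.
    """

    experiment: str = "compartments"          # or "cue_barrier"
    n_cells: int = 20
    duration: float = 1200.0                  # s per session
    dt: float = 0.02                          # s (50 Hz tracking)
    seed: int = 0

    # population
    cell_type: str = "hd"                     # cue_barrier only: "hd" | "place"
    kappa_tuning: float = 4.0
    peak_rate_range: tuple[float, float] = (20.0, 40.0)
    baseline_rate: float = 0.5
    place_sigma: float = 8.0
    place_peak_range: tuple[float, float] = (8.0, 20.0)

    # compartments experiment
    reference_mode: str = "global"            # or "local"

    # cue_barrier experiment
    rotation_magnitude: float = 90.0
    cue_gain: float = 1.0
    barrier_gain: float = 1.0
    angular_noise_sd: float = 15.0
    barrier_adjacent_gain: Optional[float] = None
    barrier_distant_gain: Optional[float] = None
    adjacency_dist: float = 10.0              # cm

    # analysis
    criteria_hd: CriteriaHD = field(default_factory=CriteriaHD)
    criteria_place: CriteriaPlace = field(default_factory=CriteriaPlace)
    motion: MotionParams = field(default_factory=MotionParams)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("criteria_hd", CriteriaHD), ("criteria_place", CriteriaPlace),
                         ("motion", MotionParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("peak_rate_range", "place_peak_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    cells: pd.DataFrame               # one row per simulated cell
    tests: dict[str, TestResult]      # named inference results
    summary: dict                     # plain-scalar summary of the tests
    config: ExperimentConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False, float_format="%.6f")
        report = {"config_hash": self.config.config_hash(),
                  "experiment": self.config.experiment,
                  "seed": self.config.seed,
                  "summary": self.summary}
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        rows = [{"test": name, "statistic": t.statistic, "p_value": t.p_value,
                 "n": t.n, "method": t.method} for name, t in self.tests.items()]
        pd.DataFrame(rows).to_csv(out / "tests.csv", index=False, float_format="%.6g")


def _test_summary(tests: dict[str, TestResult]) -> dict:
    out = {}
    for name, t in tests.items():
        out[name] = {"statistic": round(t.statistic, 6), "p_value": round(t.p_value, 6),
                     "n": t.n}
        for key in ("kappa_1", "kappa_2"):
            if key in t.extras:
                out[name][key] = round(t.extras[key], 6)
    return out


# ---------------------------------------------------------------------------
# compartment experiment
# ---------------------------------------------------------------------------

def run_compartment_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Simulate, classify, and analyze the four-compartment experiment."""
    if cfg.experiment != "compartments":
        raise ValueError("config.experiment must be 'compartments'")
    ss = np.random.SeedSequence(cfg.seed)
    s_traj, s_cells = ss.spawn(2)
    traj_seeds = s_traj.spawn(4)

    octagon = build_geometry("octagon")
    geoms = {"bracket_1": octagon, "parallel": build_geometry("parallel4"),
             "radial": build_geometry("radial4"), "bracket_2": octagon}
    trajs = {name: simulate_trajectory(g, cfg.duration, cfg.motion, seed, dt=cfg.dt)
             for (name, g), seed in zip(geoms.items(), traj_seeds)}
    log.info("compartments: simulated 4 trajectories of %.0f s (seed %d, config %s)",
             cfg.duration, cfg.seed, cfg.config_hash())

    rng = np.random.default_rng(s_cells)
    cell_seed_pool = s_cells.spawn(cfg.n_cells)
    sessions: dict[str, list] = {k: [] for k in geoms}
    cells_meta = []
    for i in range(cfg.n_cells):
        pfd = float(rng.uniform(0.0, 360.0))
        peak = float(rng.uniform(*cfg.peak_rate_range))
        params = HDCellParams(pfd=pfd, kappa_tuning=cfg.kappa_tuning,
                              peak_rate=peak, baseline_rate=cfg.baseline_rate)
        uid = f"hd_{i:03d}"
        spk_seeds = cell_seed_pool[i].spawn(4)
        for k, name in enumerate(("bracket_1", "bracket_2")):
            sessions[name].append(simulate_hd_cell(trajs[name], params, spk_seeds[k],
                                                   unit_id=uid, session_id=name))
        for k, name in enumerate(("parallel", "radial"), start=2):
            if cfg.reference_mode == "global":
                st = simulate_hd_cell(trajs[name], params, spk_seeds[k],
                                      unit_id=uid, session_id=name)
            elif cfg.reference_mode == "local":
                axes = compartment_axis_angles("parallel4" if name == "parallel"
                                               else "radial4")
                pfd_by_region = {f"compartment_{j + 1}": float(wrap360(pfd + axes[j] - axes[0]))
                                 for j in range(4)}
                st = simulate_hd_cell_by_region(trajs[name], geoms[name], pfd_by_region,
                                                params, spk_seeds[k], unit_id=uid,
                                                session_id=name)
            else:
                raise ValueError(f"unknown reference_mode {cfg.reference_mode!r}")
            sessions[name].append(st)
        cells_meta.append({"unit_id": uid, "pfd": pfd, "peak_rate": peak})

    recs = {name: SessionRecording(trajectory=trajs[name], spikes=sessions[name],
                                   geometry=geoms[name], condition_label=name,
                                   session_id=name)
            for name in geoms}

    rows = []
    for meta in cells_meta:
        uid = meta["unit_id"]
        cls = classify_hd_cell([recs["bracket_1"], recs["bracket_2"]], uid, cfg.criteria_hd)
        row = dict(meta, accepted=cls.accepted,
                   r_bracket_1=cls.r_values[0], r_bracket_2=cls.r_values[1],
                   rate_bracket_1=cls.mean_rates[0], rate_bracket_2=cls.mean_rates[1])
        if cls.accepted:
            for name in ("parallel", "radial"):
                try:
                    curves, usable = compartment_tuning_curves(recs[name], uid)
                    shifts = adjacent_compartment_shifts(curves, usable)
                    row[f"mean_shift_{name}"] = shifts.mean_shift
                    for j, s in enumerate(shifts.shifts):
                        row[f"shift_{name}_{j + 1}v{j + 2}"] = s
                except ValueError:
                    row[f"mean_shift_{name}"] = np.nan
        rows.append(row)
    cells = pd.DataFrame(rows)
    n_pass = int(cells["accepted"].sum())
    log.info("compartments: %d/%d cells pass the HD criterion", n_pass, cfg.n_cells)
    if n_pass == 0:
        raise RuntimeError("zero cells passed HD classification")

    ok = cells["accepted"] & cells.get("mean_shift_parallel", pd.Series(dtype=float)).notna() \
        & cells.get("mean_shift_radial", pd.Series(dtype=float)).notna()
    par = cells.loc[ok, "mean_shift_parallel"].to_numpy()
    rad = cells.loc[ok, "mean_shift_radial"].to_numpy()
    mc_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31))
    tests = {}
    if len(par) >= 5:
        tests["v_parallel_vs_0"] = v_test(par, 0.0)
        tests["v_radial_vs_0"] = v_test(rad, 0.0)
        try:
            tests["moore_parallel_vs_radial"] = moore_paired_test(par, rad, seed=mc_seed)
        except ValueError as exc:
            log.warning("compartments: Moore's test skipped (%s)", exc)
        if len(par) >= 10:
            tests["kappa_parallel_vs_radial"] = compare_kappa(par, rad)
    else:
        log.warning("compartments: only %d analyzable cells; inference skipped", len(par))
    summary = {"n_cells": cfg.n_cells, "n_accepted": n_pass,
               "n_analyzed": int(ok.sum()),
               "mean_shift_parallel_deg": float(wrap180(np.rad2deg(np.angle(
                   np.exp(1j * np.deg2rad(par)).mean())))),
               "mean_shift_radial_deg": float(wrap180(np.rad2deg(np.angle(
                   np.exp(1j * np.deg2rad(rad)).mean())))),
               "tests": _test_summary(tests)}
    return ExperimentResult(cells=cells, tests=tests, summary=summary, config=cfg)


# ---------------------------------------------------------------------------
# cue/barrier experiment
# ---------------------------------------------------------------------------

def _condition_geometry(condition: str):
    if condition == "cue":
        return build_geometry("octagon", cue_angle=0.0)
    return build_geometry("octagon_barrier", barrier_angle=90.0)


def run_cue_barrier_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Simulate and analyze the cue-card versus barrier rotation series."""
    if cfg.experiment != "cue_barrier":
        raise ValueError("config.experiment must be 'cue_barrier'")
    if cfg.cell_type == "hd":
        return _cue_barrier_hd(cfg)
    if cfg.cell_type == "place":
        return _cue_barrier_place(cfg)
    raise ValueError(f"unknown cell_type {cfg.cell_type!r}")


def _cue_barrier_hd(cfg: ExperimentConfig) -> ExperimentResult:
    ss = np.random.SeedSequence(cfg.seed)
    s_traj, s_cells, s_mc = ss.spawn(3)
    gains = {"cue": cfg.cue_gain, "barrier": cfg.barrier_gain}
    session_names = ("standard", "rot90", "return")
    trajs = {}
    geoms = {}
    tseeds = iter(s_traj.spawn(6))
    for cond in ("cue", "barrier"):
        geoms[cond] = _condition_geometry(cond)
        for sname in session_names:
            trajs[(cond, sname)] = simulate_trajectory(
                geoms[cond], cfg.duration, cfg.motion, next(tseeds), dt=cfg.dt)
    log.info("cue_barrier[hd]: 6 trajectories of %.0f s (seed %d)", cfg.duration, cfg.seed)

    rng = np.random.default_rng(s_cells)
    cell_pool = s_cells.spawn(cfg.n_cells)
    spikes: dict[tuple, list] = {k: [] for k in trajs}
    meta = []
    for i in range(cfg.n_cells):
        pfd = float(rng.uniform(0.0, 360.0))
        peak = float(rng.uniform(*cfg.peak_rate_range))
        base = HDCellParams(pfd=pfd, kappa_tuning=cfg.kappa_tuning,
                            peak_rate=peak, baseline_rate=cfg.baseline_rate)
        rot = cfg.rotation_magnitude if i % 2 == 0 else -cfg.rotation_magnitude
        uid = f"hd_{i:03d}"
        pool = iter(cell_pool[i].spawn(10))
        deltas = {}
        for cond in ("cue", "barrier"):
            m = CueManipulation(rot, gains[cond], cfg.angular_noise_sd)
            p_rot, d1 = apply_manipulation(base, m, seed=next(pool))
            m_back = CueManipulation(-rot, gains[cond], cfg.angular_noise_sd)
            p_ret, d2 = apply_manipulation(p_rot, m_back, seed=next(pool))
            for sname, params in zip(session_names, (base, p_rot, p_ret)):
                spikes[(cond, sname)].append(simulate_hd_cell(
                    trajs[(cond, sname)], params, next(pool), unit_id=uid,
                    session_id=f"{cond}_{sname}"))
            deltas[cond] = (d1, d2)
        meta.append({"unit_id": uid, "pfd": pfd, "peak_rate": peak, "rotation": rot,
                     "delta_cue_rot": deltas["cue"][0],
                     "delta_barrier_rot": deltas["barrier"][0]})

    recs = {k: SessionRecording(trajectory=trajs[k], spikes=spikes[k],
                                geometry=geoms[k[0]], condition_label=k[1],
                                session_id=f"{k[0]}_{k[1]}")
            for k in trajs}

    rows = []
    for m in meta:
        uid = m["unit_id"]
        row = dict(m)
        for cond in ("cue", "barrier"):
            brackets = [recs[(cond, "standard")], recs[(cond, "return")]]
            all_sess = [recs[(cond, s)] for s in session_names]
            cls = classify_hd_cell(brackets, uid, cfg.criteria_hd, all_sessions=all_sess)
            row[f"accepted_{cond}"] = cls.accepted
            if not cls.accepted:
                continue
            tcs = {s: tuning_curve(recs[(cond, s)], recs[(cond, s)].unit(uid))
                   for s in session_names}
            pairs = {"std_rot": ("standard", "rot90", m["rotation"]),
                     "rot_ret": ("rot90", "return", -m["rotation"]),
                     "std_ret": ("standard", "return", m["rotation"])}
            for key, (sa, sb, commanded) in pairs.items():
                try:
                    res = tuning_shift(tcs[sa], tcs[sb])
                    row[f"shift_{cond}_{key}"] = res.shift
                    row[f"shift_{cond}_{key}_norm"] = normalize_shift_sign(
                        res.shift, commanded)
                    row[f"maxcorr_{cond}_{key}"] = res.max_corr
                except ValueError:
                    pass
        rows.append(row)
    cells = pd.DataFrame(rows)
    cells["accepted"] = cells["accepted_cue"] & cells["accepted_barrier"]
    n_pass = int(cells["accepted"].sum())
    log.info("cue_barrier[hd]: %d/%d cells pass in both conditions", n_pass, cfg.n_cells)
    if n_pass == 0:
        raise RuntimeError("zero cells passed HD classification")

    acc = cells[cells["accepted"]]
    tests: dict[str, TestResult] = {}
    mc_seeds = iter(int(x) for x in
                    np.random.default_rng(s_mc).integers(2 ** 31, size=16))
    for key, target in (("std_rot", cfg.rotation_magnitude),
                        ("rot_ret", cfg.rotation_magnitude), ("std_ret", 0.0)):
        pair = acc[[f"shift_cue_{key}_norm", f"shift_barrier_{key}_norm"]].dropna()
        cue_s = pair[f"shift_cue_{key}_norm"].to_numpy()
        bar_s = pair[f"shift_barrier_{key}_norm"].to_numpy()
        if len(cue_s) >= 5:
            tests[f"v_cue_{key}"] = v_test(cue_s, target)
            tests[f"v_barrier_{key}"] = v_test(bar_s, target)
            try:
                tests[f"moore_{key}"] = moore_paired_test(cue_s, bar_s,
                                                          seed=next(mc_seeds))
            except ValueError as exc:
                log.warning("cue_barrier: Moore's test (%s) skipped (%s)", key, exc)
            if len(cue_s) >= 10:
                tests[f"kappa_{key}"] = compare_kappa(cue_s, bar_s)
    summary = {"n_cells": cfg.n_cells, "n_accepted": n_pass,
               "tests": _test_summary(tests)}
    return ExperimentResult(cells=cells, tests=tests, summary=summary, config=cfg)


def _cue_barrier_place(cfg: ExperimentConfig) -> ExperimentResult:
    ss = np.random.SeedSequence(cfg.seed)
    s_traj, s_cells, s_mc = ss.spawn(3)
    session_names = ("standard", "rot90")
    trajs, geoms = {}, {}
    tseeds = iter(s_traj.spawn(4))
    for cond in ("cue", "barrier"):
        geoms[cond] = _condition_geometry(cond)
        for sname in session_names:
            trajs[(cond, sname)] = simulate_trajectory(
                geoms[cond], cfg.duration, cfg.motion, next(tseeds), dt=cfg.dt)
    log.info("cue_barrier[place]: 4 trajectories of %.0f s (seed %d)", cfg.duration, cfg.seed)

    barrier = geoms["barrier"].barrier
    rng = np.random.default_rng(s_cells)
    cell_pool = s_cells.spawn(cfg.n_cells)
    spikes: dict[tuple, list] = {k: [] for k in trajs}
    meta = []
    inner = geoms["cue"].outline.buffer(-12.0)
    for i in range(cfg.n_cells):
        while True:  # field center well inside the walls
            cx_, cy_ = rng.uniform(-40, 40, size=2)
            if inner.contains(Point(cx_, cy_)):
                break
        peak = float(rng.uniform(*cfg.place_peak_range))
        base = PlaceCellParams(center=(float(cx_), float(cy_)), sigma_field=cfg.place_sigma,
                               peak_rate=peak)
        true_adj = barrier.distance(Point(base.center)) <= cfg.adjacency_dist
        rot = cfg.rotation_magnitude if i % 2 == 0 else -cfg.rotation_magnitude
        uid = f"pc_{i:03d}"
        pool = iter(cell_pool[i].spawn(8))
        row = {"unit_id": uid, "center_x": base.center[0], "center_y": base.center[1],
               "peak_rate": peak, "rotation": rot, "true_adjacent": bool(true_adj)}
        for cond in ("cue", "barrier"):
            gain = cfg.cue_gain if cond == "cue" else cfg.barrier_gain
            if cond == "barrier":
                if true_adj and cfg.barrier_adjacent_gain is not None:
                    gain = cfg.barrier_adjacent_gain
                if not true_adj and cfg.barrier_distant_gain is not None:
                    gain = cfg.barrier_distant_gain
            m = CueManipulation(rot, gain, cfg.angular_noise_sd)
            p_rot, d1 = apply_manipulation(base, m, seed=next(pool))
            for sname, params in zip(session_names, (base, p_rot)):
                spikes[(cond, sname)].append(simulate_place_cell(
                    trajs[(cond, sname)], params, next(pool), unit_id=uid,
                    session_id=f"{cond}_{sname}"))
            row[f"delta_{cond}"] = d1
            row[f"gain_{cond}"] = gain
        meta.append(row)

    recs = {k: SessionRecording(trajectory=trajs[k], spikes=spikes[k],
                                geometry=geoms[k[0]], condition_label=k[1],
                                session_id=f"{k[0]}_{k[1]}")
            for k in trajs}

    rows = []
    for m in meta:
        uid = m["unit_id"]
        row = dict(m)
        cls = classify_place_cell(recs[("cue", "standard")], uid, cfg.criteria_place)
        row["accepted"] = cls.accepted
        row["spatial_information"] = cls.spatial_information
        row["mean_rate"] = cls.mean_rate
        if cls.accepted:
            for cond in ("cue", "barrier"):
                sa, sb = recs[(cond, "standard")], recs[(cond, "rot90")]
                ua, mask_a = speed_filter(sa, sa.unit(uid), cfg.criteria_place.speed_threshold)
                ub, mask_b = speed_filter(sb, sb.unit(uid), cfg.criteria_place.speed_threshold)
                try:
                    res = map_rotation_shift(sa, sb, uid,
                                             sample_mask_a=mask_a, sample_mask_b=mask_b)
                except ValueError:
                    continue
                norm = normalize_shift_sign(res.shift, m["rotation"])
                row[f"shift_{cond}"] = res.shift
                row[f"shift_{cond}_norm"] = norm
                row[f"maxcorr_{cond}"] = res.max_corr
                row[f"response_{cond}"] = classify_rotation_response(
                    res.shift, m["rotation"])
                if cond == "barrier":
                    rm = rate_map(sa, ua, sample_mask=mask_a)
                    row["field_relation"] = classify_field_barrier_relation(
                        rm, geoms["barrier"], cfg.adjacency_dist)
        rows.append(row)
    cells = pd.DataFrame(rows)
    n_pass = int(cells["accepted"].sum())
    log.info("cue_barrier[place]: %d/%d cells pass the place criterion",
             n_pass, cfg.n_cells)
    if n_pass == 0:
        raise RuntimeError("zero cells passed place classification")

    acc = cells[cells["accepted"]].dropna(subset=["shift_cue_norm", "shift_barrier_norm"])
    cue_s = acc["shift_cue_norm"].to_numpy()
    bar_s = acc["shift_barrier_norm"].to_numpy()
    mc_seed = int(np.random.default_rng(s_mc).integers(2 ** 31))
    tests: dict[str, TestResult] = {}
    if len(cue_s) >= 5:
        tests["v_cue_vs_90"] = v_test(cue_s, cfg.rotation_magnitude)
        tests["v_barrier_vs_90"] = v_test(bar_s, cfg.rotation_magnitude)
        try:
            tests["moore_cue_vs_barrier"] = moore_paired_test(cue_s, bar_s, seed=mc_seed)
        except ValueError as exc:
            log.warning("cue_barrier: Moore's test skipped (%s)", exc)
        if len(cue_s) >= 10:
            tests["kappa_cue_vs_barrier"] = compare_kappa(cue_s, bar_s)

    strat = {}
    if "field_relation" in cells.columns:
        for rel in ("adjacent", "distant"):
            sub = acc[acc["field_relation"] == rel]
            if len(sub):
                strat[rel] = {
                    "n": int(len(sub)),
                    "pct_rotated": float(100.0 * (sub["response_barrier"] == "rotated").mean()),
                    "pct_unchanged": float(100.0 * (sub["response_barrier"] == "unchanged").mean()),
                }
    summary = {"n_cells": cfg.n_cells, "n_accepted": n_pass,
               "adjacency_stratification": strat, "tests": _test_summary(tests)}
    return ExperimentResult(cells=cells, tests=tests, summary=summary, config=cfg)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Dispatch on cfg.experiment."""
    if cfg.experiment == "compartments":
        return run_compartment_experiment(cfg)
    if cfg.experiment == "cue_barrier":
        return run_cue_barrier_experiment(cfg)
    raise ValueError(f"unknown experiment {cfg.experiment!r}")
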