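"""End-to-end pipeline: simulate (or load) a recording, smooth markers,
recover body poses, run the freeze scan, classify expansion waves, and
write a reproducible result bundle."""
from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import precision_metric, smooth_trajectories, solve_rigid_alignment
from .fitting import (fit_mechanism_frame, sequential_freeze,
                      targets_from_poses)
from .fixture import (APRIORI_FROZEN, ERROR_BODIES, PRIMARY_DOFS,
                      build_catfish_fixture, scaled_geometry)
from .io import (RunConfig, events_to_frame, mechanism_to_yaml,
                 write_marker_csv)
from .joints import select_disparate_frames
from .synthetic import (default_wave_spec, generate_wave_trajectories,
                        simulate_recording)
from .waves import (ClassifierThresholds, DoFTraces, align_and_aggregate,
                    classify_event, detect_events, prey_velocity_rc)

__all__ = ["run_pipeline", "poses_from_markers"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def poses_from_markers(markers_by_body, reference_config):
    """Per-frame body poses by rigid alignment of the reference marker
    configuration onto the observed one; frames with fewer than 3 visible
    markers yield None (masked)."""
    out = {}
    for body, trajs in markers_by_body.items():
        ref = reference_config[body]
        n = trajs[0].n_frames
        poses = []
        for f in range(n):
            obs = np.array([t.positions[f] for t in trajs])
            ok = ~np.array([t.missing[f] for t in trajs])
            if ok.sum() < 3:
                poses.append(None)
                continue
            pose, _ = solve_rigid_alignment(ref[ok], obs[ok])
            poses.append(pose)
        out[body] = poses
    return out


def run_pipeline(config: RunConfig, progress: bool = True) -> dict:
    """Run the whole analysis on a seeded synthetic recording.

    Stages: simulate -> smooth -> pose recovery -> precision benchmark ->
    freeze scan (on the most disparate frames) -> per-frame five-DoF fit ->
    event detection/classification -> aligned aggregates (+ prey velocity).
    Outputs are deterministic given the config; every file name is prefixed
    by nothing but lives under ``config.out_dir`` together with a machine
    readable run log carrying the config hash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "python": platform.python_version(),
                 "config": config.model_dump(),
                 "config_hash": config.config_hash(), "stages": []}
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            if progress:
                print(f"[{name}] ...", flush=True)
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - reported with stage name
                log["stages"].append({"name": name, "status": "failed",
                                      "error": str(e)})
                (out_dir / "run_log.json").write_text(
                    json.dumps(log, indent=2, default=str))
                raise PipelineError(name, e) from e
            log["stages"].append({
                "name": name, "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3)})
        return deco

    @stage("simulate")
    def _simulate():
        geo = scaled_geometry(config.scale_factor)
        mech, par, fps = build_catfish_fixture(geo)
        specs = [default_wave_spec(k) for k in config.wave_classes]
        wave = generate_wave_trajectories(specs, config.n_events,
                                          fs=config.frame_rate_hz,
                                          seed=config.seed)
        rec = simulate_recording(mech, par, wave, fps,
                                 markers_per_body=config.markers_per_body,
                                 noise_mm=config.noise_mm,
                                 head_length=geo.head_length,
                                 seed=config.seed + 10)
        results.update(mech=mech, par=par, fps=fps, rec=rec, wave=wave,
                       head_length=geo.head_length)
        write_marker_csv(out_dir / "markers.csv", rec.markers)
        mechanism_to_yaml(mech, par, out_dir / "mechanism.yaml")

    @stage("smooth")
    def _smooth():
        rec = results["rec"]
        results["smoothed"] = smooth_trajectories(
            rec.markers, cutoff=config.smoothing_cutoff_hz)

    @stage("poses")
    def _poses():
        rec = results["rec"]
        by_body: dict = {}
        for tr in results["smoothed"]:
            by_body.setdefault(tr.body, []).append(tr)
        # reference configuration = marker sites in the body frame; recover
        # them from the simulation's first-frame pose
        ref_cfg = {}
        for b, trs in by_body.items():
            p0 = rec.poses[b][0]
            ref_cfg[b] = np.array(
                [p0.inverse().apply(t.positions[0]) for t in trs])
        results["markers_by_body"] = by_body
        results["body_poses"] = poses_from_markers(by_body, ref_cfg)

    @stage("precision")
    def _precision():
        pm = precision_metric(results["markers_by_body"],
                              n_frames=min(50, len(results["rec"].params_true)),
                              seed=config.seed)
        results["precision"] = pm
        results["precision_mean"] = float(np.nanmean(list(pm.values())))

    @stage("freeze_scan")
    def _freeze():
        mech, par, fps = results["mech"], results["par"], results["fps"]
        rec = results["rec"]
        bodies = [b for b in ERROR_BODIES if b in rec.poses]
        all_targets = []
        for f in range(len(rec.params_true)):
            poses = {b: rec.poses[b][f] for b in bodies}
            all_targets.append(targets_from_poses(poses, fps, bodies))
        configs = np.stack([np.concatenate([t[b].ravel() for b in bodies])
                            for t in all_targets])
        sel = select_disparate_frames(configs,
                                      min(config.freeze_frames, len(configs)))
        start_free = [l for l in par.labels if l not in APRIORI_FROZEN]
        means = {lab: float(rec.params_true[lab].mean())
                 for lab in par.labels}
        curve = sequential_freeze(
            mech, par, [all_targets[i] for i in sel], fps, start_free,
            means, head_length=results["head_length"],
            max_steps=config.freeze_max_steps)
        results["curve"] = curve
        curve.to_frame().to_csv(out_dir / "freeze_curve.csv", index=False)

    @stage("dof_traces")
    def _traces():
        mech, par, fps = results["mech"], results["par"], results["fps"]
        rec = results["rec"]
        bodies = [b for b in ERROR_BODIES if b in rec.poses]
        free = list(PRIMARY_DOFS) + ["A", "B"]
        rows, q = [], None
        for f in range(len(rec.params_true)):
            poses = {b: rec.poses[b][f] for b in bodies}
            fr = fit_mechanism_frame(mech, par, targets_from_poses(
                poses, fps, bodies), fps, free, q_init=q,
                max_nfev=80, xtol=1e-9)
            q = fr.q
            rows.append({lab: fr.params[lab] for lab in PRIMARY_DOFS})
        results["fitted_params"] = pd.DataFrame(rows)

    @stage("classify")
    def _classify():
        traces = DoFTraces.from_params(results["fitted_params"],
                                       config.frame_rate_hz)
        th = ClassifierThresholds(
            amplitude_dominance=config.amplitude_dominance,
            peak_order_margin_s=config.peak_order_margin_s,
            slow_rise_s=config.slow_rise_s)
        events = detect_events(traces, window_s=config.event_window_s,
                               prominence=config.peak_prominence)
        for e in events:
            classify_event(e, th)
        results["events"] = events
        events_to_frame(events).to_csv(out_dir / "events.csv", index=False)

    @stage("aggregate")
    def _aggregate():
        events = results["events"]
        rec = results["rec"]
        for klass in sorted({e.klass for e in events}):
            agg = align_and_aggregate(events, klass,
                                      grid_hz=config.frame_rate_hz)
            if rec.prey is not None:
                pv = prey_velocity_rc(rec.prey, events, klass,
                                      grid_hz=config.frame_rate_hz)
                agg = agg.merge(pv, on="t_rel_s", how="left")
            agg.to_csv(out_dir / f"aggregate_{klass}.csv", index=False)

    log["precision_mm"] = results.get("precision")
    log["n_events"] = len(results.get("events", []))
    log["event_classes"] = [e.klass for e in results.get("events", [])]
    curve = results.get("curve")
    if curve is not None:
        log["freeze_order"] = curve.freeze_order
        log["median_errors_mm"] = [s.median_mm for s in curve.steps]
    (out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2, default=str))
    results["log"] = log
    return results
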