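"""File formats and run configuration.

CSV dialects (all units mm, seconds, Hz):

* marker CSV: ``frame,time_s,marker,body,x_mm,y_mm,z_mm`` — blank
  coordinates mean the marker was not reconstructed in that frame;
* transform CSV: ``frame,body,r11..r33,t1,t2,t3`` — row-major rotation
  matrix plus translation per body per frame;
* events CSV and per-class aggregate CSV as written by the pipeline.

Mechanisms and parameterizations round-trip through YAML; struts are stored
by their anchors and rebuilt, so the file never exposes the internal
half-link bookkeeping.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .core import MarkerTrajectory, Pose
from .joints import JointType
from .mechanism import DoFParameterization, Mechanism

__all__ = [
    "read_marker_csv",
    "write_marker_csv",
    "read_transform_csv",
    "write_transform_csv",
    "mechanism_to_yaml",
    "mechanism_from_yaml",
    "events_to_frame",
    "RunConfig",
]

_MARKER_COLS = ["frame", "time_s", "marker", "body", "x_mm", "y_mm", "z_mm"]


class MarkerCSVError(ValueError):
    pass


def read_marker_csv(path) -> list[MarkerTrajectory]:
    """Parse a marker CSV into typed trajectories with missing-frame masks.

    The frame rate is inferred from the ``time_s`` column; all markers of a
    recording must share the frame count.  Malformed rows raise with their
    line number.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _MARKER_COLS if c not in df.columns]
    if missing_cols:
        raise MarkerCSVError(f"{path}: missing columns {missing_cols}")
    bad = df.index[df["frame"].isna() | df["marker"].isna()]
    if len(bad):
        raise MarkerCSVError(f"{path}: malformed row at line {bad[0] + 2}")
    frames = np.sort(df["frame"].unique())
    n = len(frames)
    t = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
    if n > 1:
        dt = np.diff(t)
        # timestamps are typically printed with ~6 significant digits
        if np.any(dt <= 0) or np.ptp(dt) > 1e-3 * dt.mean():
            raise MarkerCSVError(f"{path}: time_s is not uniformly increasing")
        fr = 1.0 / float(dt.mean())
    else:
        fr = 1.0
    out = []
    fidx = {f: i for i, f in enumerate(frames)}
    for (marker, body), g in df.groupby(["marker", "body"], sort=True):
        pos = np.full((n, 3), np.nan)
        rows = [fidx[f] for f in g["frame"]]
        pos[rows] = g[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        out.append(MarkerTrajectory(str(marker), str(body), pos, fr))
    return out


def write_marker_csv(path, trajectories: list[MarkerTrajectory]) -> None:
    rows = []
    for tr in trajectories:
        for f in range(tr.n_frames):
            x, y, z = tr.positions[f]
            rows.append({"frame": f, "time_s": f / tr.frame_rate,
                         "marker": tr.marker, "body": tr.body,
                         "x_mm": "" if tr.missing[f] else x,
                         "y_mm": "" if tr.missing[f] else y,
                         "z_mm": "" if tr.missing[f] else z})
    pd.DataFrame(rows, columns=_MARKER_COLS).to_csv(path, index=False)


def read_transform_csv(path) -> dict[str, list[Pose]]:
    """Per-body rigid-transform trajectories; rotations are validated (and
    re-orthonormalized within 1e-6) on read."""
    df = pd.read_csv(path)
    rcols = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    need = ["frame", "body"] + rcols + ["t1", "t2", "t3"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise MarkerCSVError(f"{path}: missing columns {missing}")
    out: dict[str, list[Pose]] = {}
    for body, g in df.groupby("body", sort=True):
        g = g.sort_values("frame")
        poses = []
        for _, row in g.iterrows():
            R = row[rcols].to_numpy(dtype=float).reshape(3, 3)
            p = Pose(R, row[["t1", "t2", "t3"]].to_numpy(dtype=float))
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                raise MarkerCSVError(
                    f"{path}: non-orthonormal rotation for body {body}")
            poses.append(p.orthonormalize())
        out[str(body)] = poses
    return out


def write_transform_csv(path, poses: dict[str, list[Pose]]) -> None:
    rcols = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    rows = []
    for body in sorted(poses):
        for f, p in enumerate(poses[body]):
            row = {"frame": f, "body": body}
            row.update(dict(zip(rcols, p.rotation.ravel())))
            row.update(dict(zip(("t1", "t2", "t3"), p.translation)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def mechanism_to_yaml(mech: Mechanism, par: DoFParameterization | None = None,
                      path=None) -> str:
    strut_items = {j for s in mech.struts
                   for j in (s.joint_a, s.joint_p, s.joint_b)}
    strut_links = {l for s in mech.struts for l in (s.half_a, s.half_b)}
    doc: dict = {
        "name": mech.name,
        "links": [{"name": l, **({"fixed": True}
                                 if l == mech.fixed_link else {})}
                  for l in mech.links if l not in strut_links],
        "joints": [{"name": j.name, "parent": j.parent, "child": j.child,
                    "type": j.kind.value,
                    "center_mm": [float(v) for v in j.center],
                    "axes": [[float(v) for v in ax] for ax in j.axes]}
                   for j in mech.joints if j.name not in strut_items],
        "struts": [{"name": s.name, "body_a": s.body_a,
                    "anchor_a_mm": [float(v) for v in
                                    mech.joint(s.joint_a).center],
                    "body_b": s.body_b,
                    "anchor_b_mm": [float(v) for v in
                                    mech.joint(s.joint_b).center]}
                   for s in mech.struts],
    }
    if par is not None:
        doc["parameterization"] = {
            "labels": list(par.labels),
            "matrix": [[float(v) for v in row] for row in par.matrix],
            "offset": [float(v) for v in par.offset],
            "groups": {k: list(v) for k, v in par.groups.items()},
            "descriptions": dict(par.descriptions),
        }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def mechanism_from_yaml(src) -> tuple[Mechanism, DoFParameterization | None]:
    if isinstance(src, (str, Path)) and "\n" not in str(src):
        text = Path(src).read_text()
    else:
        text = str(src)
    doc = yaml.safe_load(text)
    m = Mechanism(doc.get("name", "mechanism"))
    for l in doc.get("links", []):
        m.add_link(l["name"], fixed=bool(l.get("fixed", False)))
    for j in doc.get("joints", []):
        m.add_joint(j["name"], j["parent"], j["child"],
                    JointType(j["type"]), j["center_mm"], j["axes"])
    for s in doc.get("struts", []):
        m.add_strut(s["name"], s["body_a"], s["anchor_a_mm"],
                    s["body_b"], s["anchor_b_mm"])
    m.finalize()
    par = None
    pdoc = doc.get("parameterization")
    if pdoc:
        par = DoFParameterization(
            mechanism=m, labels=list(pdoc["labels"]),
            matrix=np.asarray(pdoc["matrix"], dtype=float),
            offset=np.asarray(pdoc["offset"], dtype=float),
            groups={k: list(v) for k, v in pdoc.get("groups", {}).items()},
            descriptions=dict(pdoc.get("descriptions", {})))
    return m, par


def events_to_frame(events) -> pd.DataFrame:
    """Events table: one row per event with peaks per DoF."""
    from .waves import DOF_NAMES
    rows = []
    for e in events:
        row = {"event_id": e.event_id, "class": e.klass,
               "t_ref_s": e.t_ref, "t_start_s": e.start, "t_end_s": e.end}
        for name in DOF_NAMES:
            row[f"peak_time_{name}"] = e.peak_times.get(name, np.nan)
            row[f"peak_amp_{name}"] = e.peak_amps.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    Thresholds whose values are this package's own calls (rather than
    quantities with published backing) are grouped under
    ``artifact_decisions`` in the serialized form for auditability.
    """

    seed: int = 0
    out_dir: str = "skullkin_out"
    frame_rate_hz: float = Field(300.0, gt=0)
    smoothing_cutoff_hz: float = Field(25.0, gt=0)
    noise_mm: float = Field(0.08, ge=0)
    markers_per_body: int = Field(4, ge=3)
    n_events: int = Field(3, ge=1)
    wave_classes: list[str] = ["rostrocaudal", "caudorostral", "compressive"]
    freeze_frames: int = Field(15, ge=1)
    freeze_max_steps: int | None = None
    event_window_s: float = Field(0.5, gt=0)
    peak_prominence: float = Field(0.05, gt=0)
    amplitude_dominance: float = Field(0.1, gt=0)
    peak_order_margin_s: float = Field(0.005, ge=0)
    slow_rise_s: float = Field(0.25, gt=0)
    scale_factor: float = Field(1.0, gt=0)

    _ARTIFACT_DECISIONS = ("smoothing_cutoff_hz", "markers_per_body",
                           "amplitude_dominance", "peak_order_margin_s",
                           "slow_rise_s", "peak_prominence")

    def to_yaml(self, path=None) -> str:
        data = self.model_dump()
        doc = {k: v for k, v in data.items()
               if k not in self._ARTIFACT_DECISIONS}
        doc["artifact_decisions"] = {k: data[k]
                                     for k in self._ARTIFACT_DECISIONS}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        if isinstance(src, (str, Path)) and "\n" not in str(src):
            text = Path(src).read_text()
        else:
            text = str(src)
        doc = yaml.safe_load(text) or {}
        doc.update(doc.pop("artifact_decisions", {}))
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
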