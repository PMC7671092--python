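"""Joint primitives and fitting of joint models to rigid-body motion.

Four joint types connect pairs of skeletal elements: revolute (hinge, 1 DoF),
universal (saddle, 2 DoF), spherical (ball-in-socket, 3 DoF) and prismatic
(slider, 1 DoF).  A joint model is fit to the observed relative motion of an
articulated body pair by optimizing its center and axes so that landmarks
("fit points") animated through the joint match the landmarks animated by the
observed rigid transforms, in the RMS sense.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .core import FitPointSet, Pose, rms_point_error

__all__ = [
    "JointType",
    "JointModel",
    "Strut",
    "joint_transform",
    "fit_joint_model",
    "select_joint_model",
    "select_disparate_frames",
]


class JointType(Enum):
    REVOLUTE = "revolute"
    UNIVERSAL = "universal"
    SPHERICAL = "spherical"
    PRISMATIC = "prismatic"

    @property
    def dof(self) -> int:
        return {JointType.REVOLUTE: 1, JointType.UNIVERSAL: 2,
                JointType.SPHERICAL: 3, JointType.PRISMATIC: 1}[self]

    @property
    def n_axes(self) -> int:
        return self.dof


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(axis, float) * float(angle)).as_matrix()


@dataclass
class JointModel:
    """A fitted (or specified) joint: type, center, axes and per-frame coordinates.

    ``center`` is in the parent frame (mm); ``axes`` holds one unit row per
    DoF.  ``coordinates`` is (n_frames, dof): rotation angles in radians, or
    slide in mm for a prismatic joint.  ``fit_rms`` is the RMS fit-point error
    in mm.  ``meta`` records provenance (selection rule, convergence flag...).
    """

    type: JointType
    center: np.ndarray
    axes: np.ndarray
    coordinates: np.ndarray | None = None
    fit_rms: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.axes.shape != (self.type.n_axes, 3):
            raise ValueError(
                f"{self.type.value} joint needs {self.type.n_axes} axes")
        norms = np.linalg.norm(self.axes, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-length axis")
        self.axes = self.axes / norms[:, None]
        if self.type is JointType.UNIVERSAL:
            if np.linalg.matrix_rank(self.axes, tol=1e-8) < 2:
                raise ValueError("universal-joint axes are linearly dependent")
        if self.coordinates is not None:
            self.coordinates = np.atleast_2d(
                np.asarray(self.coordinates, dtype=float))
            if self.coordinates.shape[1] != self.type.dof:
                raise ValueError("coordinate count per frame must equal dof")


@dataclass
class Strut:
    """Compliant soft-tissue element: a spherical-prismatic-spherical chain.

    Represents a ligament or muscle tying two bodies together; the prismatic
    DoF is its length change and the ball ends let it swivel freely.
    """

    name: str
    body_a: str
    anchor_a: np.ndarray
    body_b: str
    anchor_b: np.ndarray

    def __post_init__(self):
        self.anchor_a = np.asarray(self.anchor_a, dtype=float).reshape(3)
        self.anchor_b = np.asarray(self.anchor_b, dtype=float).reshape(3)
        if self.rest_length <= 0:
            raise ValueError("strut rest length must be > 0")

    @property
    def rest_length(self) -> float:
        return float(np.linalg.norm(self.anchor_b - self.anchor_a))

    @property
    def axis(self) -> np.ndarray:
        return (self.anchor_b - self.anchor_a) / self.rest_length


def joint_transform(model: JointModel, coords: np.ndarray) -> Pose:
    """Child-relative-to-parent Pose of a joint at the given coordinates.

    Zero coordinates give the identity.  Rotational joints rotate about axes
    through ``center`` (intrinsic composition, first axis outermost);
    prismatic joints translate along their axis.
    """
    q = np.atleast_1d(np.asarray(coords, dtype=float))
    if q.shape != (model.type.dof,):
        raise ValueError(f"expected {model.type.dof} coordinates, got {q.shape}")
    if model.type is JointType.PRISMATIC:
        return Pose(np.eye(3), model.axes[0] * q[0])
    R = np.eye(3)
    for axis, angle in zip(model.axes, q):
        R = R @ _rot(axis, angle)
    c = model.center
    return Pose(R, c - R @ c)


# ---------------------------------------------------------------------------
# per-frame optimal coordinates (inner solves, closed form where possible)

def _best_revolute_angle(u, c, P, Y):
    r = P - c
    r_par = np.outer(r @ u, u)
    r_perp = r - r_par
    s = (Y - c) - r_par
    cross = np.cross(np.broadcast_to(u, r_perp.shape), r_perp)
    return float(np.arctan2(np.sum(s * cross), np.sum(s * r_perp)))


def _frame_coords(jtype: JointType, center, axes, P, Y, q0=None):
    """Optimal joint coordinates mapping body points P toward targets Y."""
    c = center
    if jtype is JointType.REVOLUTE:
        return np.array([_best_revolute_angle(axes[0], c, P, Y)])
    if jtype is JointType.SPHERICAL:
        rot, _ = Rotation.align_vectors(Y - c, P - c)
        R = rot.as_matrix()
        # express as intrinsic angles about the model axes
        M = np.column_stack(axes)  # joint axes as columns
        ang = Rotation.from_matrix(M.T @ R @ M).as_euler("XYZ")
        return np.asarray(ang)
    if jtype is JointType.PRISMATIC:
        return np.array([float(np.mean((Y - P) @ axes[0]))])
    if jtype is JointType.UNIVERSAL:
        u1, u2 = axes
        q1, q2 = (0.0, 0.0) if q0 is None else (float(q0[0]), float(q0[1]))
        for _ in range(8):
            R2 = _rot(u2, q2)
            P2 = c + (P - c) @ R2.T
            q1 = _best_revolute_angle(u1, c, P2, Y)
            R1 = _rot(u1, q1)
            Y2 = c + (Y - c) @ R1
            q2 = _best_revolute_angle(u2, c, P, Y2)
        return np.array([q1, q2])
    raise ValueError(jtype)


def _geometry_pack(jtype: JointType, x):
    """Unpack optimizer vector -> (center, axes)."""

    def sph(t, p):
        st = np.sin(t)
        return np.array([st * np.cos(p), st * np.sin(p), np.cos(t)])

    if jtype is JointType.REVOLUTE:
        return x[:3], np.array([sph(x[3], x[4])])
    if jtype is JointType.SPHERICAL:
        # axes of a ball joint are a coordinate convention, not geometry
        return x[:3], np.eye(3)
    if jtype is JointType.PRISMATIC:
        return np.zeros(3), np.array([sph(x[0], x[1])])
    if jtype is JointType.UNIVERSAL:
        return x[:3], np.array([sph(x[3], x[4]), sph(x[5], x[6])])
    raise ValueError(jtype)


def _geometry_init(jtype: JointType, poses: list[Pose], fit_points):
    """Initial center from the classic fixed-point estimate; axes from the
    principal directions of the relative angular displacement distribution."""
    rotvecs = np.array([Rotation.from_matrix(p.rotation).as_rotvec()
                        for p in poses])
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for p in poses:
        D = p.rotation - np.eye(3)
        A += D.T @ D
        b -= D.T @ p.translation
    try:
        c0 = np.linalg.lstsq(A + 1e-9 * np.eye(3), b, rcond=None)[0]
    except np.linalg.LinAlgError:
        c0 = fit_points.mean(axis=0)
    if np.linalg.norm(c0 - fit_points.mean(axis=0)) > 100 * np.ptp(fit_points):
        c0 = fit_points.mean(axis=0)
    U, s, Vt = np.linalg.svd(rotvecs - 0.0, full_matrices=False)
    dirs = Vt  # principal axes of angular motion
    if np.linalg.norm(rotvecs) < 1e-12:
        dirs = np.eye(3)

    def angles(v):
        v = v / max(np.linalg.norm(v), 1e-12)
        return [float(np.arccos(np.clip(v[2], -1, 1))),
                float(np.arctan2(v[1], v[0]))]

    if jtype is JointType.REVOLUTE:
        return np.concatenate([c0, angles(dirs[0])])
    if jtype is JointType.SPHERICAL:
        return np.asarray(c0)
    if jtype is JointType.PRISMATIC:
        ts = np.array([p.translation for p in poses])
        _, _, Vt2 = np.linalg.svd(ts - ts.mean(axis=0), full_matrices=False)
        return np.array(angles(Vt2[0]))
    if jtype is JointType.UNIVERSAL:
        return np.concatenate([c0, angles(dirs[0]), angles(dirs[1])])
    raise ValueError(jtype)


def fit_joint_model(relative_poses: list[Pose], jtype: JointType,
                    fit_points: FitPointSet, n_restarts: int = 5,
                    seed: int = 0, max_nfev: int = 200) -> JointModel:
    """Fit a joint model of the given type to observed relative motion.

    ``relative_poses`` is the per-frame pose of the child body relative to the
    parent.  The joint geometry (center/axes) is optimized by bounded
    nonlinear least squares with seeded random restarts; at every candidate
    geometry the per-frame joint coordinates are solved in closed form
    (revolute/spherical/prismatic) or by coordinate descent (universal).

    Returns a :class:`JointModel` whose ``fit_rms`` is the RMS distance (mm)
    between fit points animated by the joint and by the observed poses.
    """
    if len(relative_poses) < 2 * jtype.dof:
        raise ValueError("need at least 2*dof frames of motion")
    P = fit_points.points
    targets = np.stack([p.apply(P) for p in relative_poses])
    rng = np.random.default_rng(seed)

    def residuals(x):
        center, axes = _geometry_pack(jtype, x)
        res = np.empty((len(relative_poses), P.shape[0], 3))
        q_prev = None
        for t in range(len(relative_poses)):
            q = _frame_coords(jtype, center, axes, P, targets[t], q_prev)
            q_prev = q
            model = _model_points(jtype, center, axes, q, P)
            res[t] = model - targets[t]
        return res.ravel()

    x0 = _geometry_init(jtype, relative_poses, P)
    scale = max(float(np.ptp(P)), 1.0)
    best = None
    for r in range(max(1, n_restarts)):
        xi = x0 if r == 0 else x0 + rng.normal(
            0, 1, size=x0.shape) * np.where(np.arange(len(x0)) < 3
                                            if jtype is not JointType.PRISMATIC
                                            else False, 0.2 * scale, 0.5)
        try:
            sol = least_squares(residuals, xi, xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("joint fitting failed for all restarts")
    center, axes = _geometry_pack(jtype, best.x)
    coords = []
    q_prev = None
    for t in range(len(relative_poses)):
        q = _frame_coords(jtype, center, axes, P, targets[t], q_prev)
        coords.append(q)
        q_prev = q
    coords = np.asarray(coords)
    model_pts = np.stack([
        _model_points(jtype, center, axes, coords[t], P)
        for t in range(len(relative_poses))])
    fit_rms = rms_point_error(model_pts.reshape(-1, 3), targets.reshape(-1, 3))
    return JointModel(jtype, center, axes, coords, fit_rms,
                      meta={"converged": bool(best.status > 0),
                            "n_restarts": n_restarts, "cost": float(best.cost)})


def _model_points(jtype, center, axes, q, P):
    model = JointModel(jtype, center, axes)
    return joint_transform(model, q).apply(P)


def select_joint_model(fits: dict[JointType, JointModel], precision: float,
                       k_precision: float = 1.5, rel_tol: float = 0.10,
                       ) -> JointModel:
    """Pick the lowest-DoF rotary joint model justified by the data.

    A lower-DoF model is accepted if its fit RMS is within ``k_precision``
    times the tracking precision, or within ``(1+rel_tol)`` of the spherical
    model's RMS; otherwise the next DoF up is considered.  The spherical model
    is always returnable, and ties in error resolve to the lowest DoF.
    """
    for req in (JointType.REVOLUTE, JointType.UNIVERSAL, JointType.SPHERICAL):
        if req not in fits:
            raise ValueError(f"missing fit for {req.value}")
    sph_rms = fits[JointType.SPHERICAL].fit_rms
    threshold = max(k_precision * precision, (1.0 + rel_tol) * sph_rms)
    for jt in (JointType.REVOLUTE, JointType.UNIVERSAL, JointType.SPHERICAL):
        if fits[jt].fit_rms <= threshold:
            chosen = fits[jt]
            chosen.meta = dict(chosen.meta)
            chosen.meta["selection"] = {
                "rule": "lowest DoF with fit_rms <= "
                        "max(k_precision*precision, (1+rel_tol)*spherical_rms)",
                "threshold_mm": float(threshold),
                "k_precision": k_precision,
                "rel_tol": rel_tol,
                "precision_mm": float(precision),
                "candidates_mm": {t.value: float(m.fit_rms)
                                  for t, m in fits.items()},
            }
            return chosen
    return fits[JointType.SPHERICAL]  # unreachable: threshold >= sph_rms


def select_disparate_frames(data: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximin selection of the k most disparate frames.

    ``data`` is (n_frames, ...) — fit-point configurations or coordinate
    vectors; distances are RMS over the flattened per-frame values.  The
    first pick is the frame farthest from the global mean; each subsequent
    pick maximizes the minimum distance to the already-selected set.  Ties
    resolve to the lowest frame index, making the selection deterministic and
    permutation-consistent.  Returns sorted frame indices.
    """
    X = np.asarray(data, dtype=float).reshape(len(data), -1)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds frame count {n}")
    if k == n:
        return np.arange(n)
    d0 = np.linalg.norm(X - X.mean(axis=0), axis=1)
    first = int(np.argmax(np.round(d0, 12)))
    selected = [first]
    mind = np.linalg.norm(X - X[first], axis=1)
    while len(selected) < k:
        mind[selected] = -np.inf
        nxt = int(np.argmax(np.round(mind, 12)))
        selected.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(X - X[nxt], axis=1))
    return np.sort(np.asarray(selected))
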