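"""Rigid-body math, marker-trajectory containers, alignment, smoothing and
the motion-capture quality benchmarks.

Conventions used throughout the package: distances in mm, time in seconds,
frequencies in Hz, angles in radians (degrees only at I/O boundaries).
Anatomical frame: +x rostral->caudal, +y left->right, +z ventral->dorsal,
origin at the neurocranium.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "MarkerTrajectory",
    "FitPointSet",
    "solve_rigid_alignment",
    "rms_point_error",
    "smooth_trajectories",
    "precision_metric",
    "procrustes_consensus",
]

_ORTHO_TOL = 1e-9


class DegenerateConfigurationError(ValueError):
    """Raised when a point configuration cannot support a rigid alignment."""


@dataclass(frozen=True)
class Pose:
    """A proper rigid transform: ``x_world = rotation @ x_body + translation``.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1;
    ``translation`` is in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def validate(self, tol: float = _ORTHO_TOL) -> "Pose":
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=max(tol, 1e-12)):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        return self

    def orthonormalize(self) -> "Pose":
        """Project the rotation back onto SO(3) (nearest by Frobenius norm)."""
        U, _, Vt = np.linalg.svd(self.rotation)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1.0
            R = U @ Vt
        return Pose(R, self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """``self`` then applied after ``other``: result maps other's body frame."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "Pose") -> "Pose":
        return self.compose(other)

    def inverse(self) -> "Pose":
        Rt = self.rotation.T
        return Pose(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n,3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    @staticmethod
    def from_matrix(T: np.ndarray) -> "Pose":
        T = np.asarray(T, dtype=float)
        return Pose(T[:3, :3], T[:3, 3])


@dataclass
class MarkerTrajectory:
    """Per-frame 3D positions of one marker rigidly attached to one body.

    ``positions`` is (n_frames, 3) in mm; frames where the marker was not
    reconstructed are flagged in ``missing`` and hold NaN coordinates.
    """

    marker: str
    body: str
    positions: np.ndarray
    frame_rate: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")
        if self.missing is None:
            self.missing = np.isnan(self.positions).any(axis=1)
        self.missing = np.asarray(self.missing, dtype=bool).reshape(-1)
        if self.missing.shape[0] != self.positions.shape[0]:
            raise ValueError("missing mask length != frame count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class FitPointSet:
    """Exactly three non-collinear landmarks, in the body frame (mm).

    Three points are the minimum that pin a rigid body's full pose, which is
    why model-vs-observed error is scored on them.
    """

    body: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] != 3:
            raise ValueError("a fit point set holds exactly three landmarks")
        _require_noncollinear(self.points)


def _require_noncollinear(points: np.ndarray, tol: float = 1e-9) -> None:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if len(s) < 2 or s[1] <= tol * max(s[0], 1.0):
        raise DegenerateConfigurationError("points are collinear or coincident")


def solve_rigid_alignment(points_a: np.ndarray, points_b: np.ndarray,
                          ) -> tuple[Pose, float]:
    """Least-squares rigid transform mapping ``points_a`` onto ``points_b``.

    Returns the Pose minimizing sum of squared paired distances (Kabsch via
    SVD) and the RMS residual in mm.  Requires >= 3 paired non-collinear
    points; raises :class:`DegenerateConfigurationError` otherwise.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("point sets must have matching shapes")
    if a.shape[0] < 3:
        raise DegenerateConfigurationError("need at least 3 paired points")
    _require_noncollinear(a)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    pose = Pose(R, t)
    resid = rms_point_error(pose.apply(a), b)
    return pose, resid


def rms_point_error(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """sqrt(mean squared Euclidean distance) between two point configurations."""
    a = np.asarray(config_a, dtype=float).reshape(-1, 3)
    b = np.asarray(config_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("configurations must have matching shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _interpolate_missing(x: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Linearly fill masked frames per column (edge frames held constant)."""
    out = x.copy()
    idx = np.arange(x.shape[0])
    good = ~missing
    if good.sum() == 0:
        raise ValueError("trajectory has no valid frames")
    for k in range(x.shape[1]):
        out[missing, k] = np.interp(idx[missing], idx[good], x[good, k])
    return out


def smooth_trajectories(markers, cutoff: float = 25.0, order: int = 4):
    """Zero-phase low-pass filter marker trajectories.

    A 4th-order Butterworth applied forward-backward (``filtfilt``), the
    standard treatment for 300 Hz skeletal kinematics.  Missing frames are
    linearly interpolated before filtering and re-masked afterwards.
    Accepts one :class:`MarkerTrajectory` or a list; ``cutoff`` must be below
    the Nyquist frequency.
    """
    single = isinstance(markers, MarkerTrajectory)
    traj_list = [markers] if single else list(markers)
    out = []
    for tr in traj_list:
        nyq = tr.frame_rate / 2.0
        if cutoff >= nyq:
            raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
        filled = _interpolate_missing(tr.positions, tr.missing)
        b, a = signal.butter(order // 2, cutoff / nyq)
        # filtfilt doubles the effective order; order//2 sections keep the
        # stated net order.
        if filled.shape[0] > 3 * max(len(a), len(b)):
            sm = signal.filtfilt(b, a, filled, axis=0)
        else:  # too short to filter stably; leave interpolated values
            sm = filled
        sm = np.array(sm)
        sm[tr.missing] = np.nan
        out.append(MarkerTrajectory(tr.marker, tr.body, sm, tr.frame_rate,
                                    tr.missing.copy()))
    return out[0] if single else out


def _frame_configs(trajectories: list[MarkerTrajectory]) -> np.ndarray:
    """(n_frames, n_markers, 3) stack for markers sharing one body."""
    n = {t.n_frames for t in trajectories}
    if len(n) != 1:
        raise ValueError("markers of one body must share a frame count")
    return np.stack([t.positions for t in trajectories], axis=1)


def precision_metric(markers_by_body: dict[str, list[MarkerTrajectory]],
                     n_frames: int = 50, seed: int | None = None,
                     ) -> dict[str, float]:
    """Tracking-precision benchmark, per body, in mm.

    For each body, the intra-body marker configuration of ``n_frames``
    randomly sampled motion frames is rigidly aligned to the mean (consensus)
    configuration; the reported value is the RMS deviation of the aligned
    configurations from that mean.  It captures calibration error, tracking
    noise and non-rigidity of the element, independent of how the body moved.

    Frames are sampled without replacement when enough are available (with
    replacement otherwise).  Bodies with fewer than 3 simultaneously visible
    markers are skipped with a warning entry of NaN.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for body, trajs in markers_by_body.items():
        configs = _frame_configs(trajs)
        visible = ~np.stack([t.missing for t in trajs], axis=1)
        ok = visible.all(axis=1)
        frames = np.flatnonzero(ok)
        if configs.shape[1] < 3 or len(frames) == 0:
            import warnings
            warnings.warn(f"body {body!r}: fewer than 3 usable markers; "
                          "precision not computed")
            out[body] = float("nan")
            continue
        if len(frames) >= n_frames:
            sel = rng.choice(frames, size=n_frames, replace=False)
        else:
            sel = rng.choice(frames, size=n_frames, replace=True)
        shapes = [configs[f] for f in sorted(sel)]
        if len(shapes) == 1:   # one frame vs its own mean: exactly zero
            out[body] = 0.0
            continue
        _, devs = procrustes_consensus(shapes)
        out[body] = float(np.sqrt(np.mean(np.square(devs))))
    return out


def procrustes_consensus(shapes: list[np.ndarray], scale: bool = False,
                         max_iter: int = 50, tol: float = 1e-12,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least-squares superimposition of landmark sets.

    Each shape (k,3) is aligned by rotation+translation (and optionally
    uniform scale, off by default so deviations stay in mm) to an iteratively
    re-estimated consensus (the mean of aligned shapes).  Returns
    ``(consensus, deviations)`` where ``deviations[i]`` is the RMS distance
    of aligned shape i from the consensus.
    """
    shapes = [np.asarray(s, dtype=float).reshape(-1, 3) for s in shapes]
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    k = shapes[0].shape[0]
    if any(s.shape[0] != k for s in shapes):
        raise ValueError("inconsistent landmark counts")
    aligned = [s - s.mean(axis=0) for s in shapes]
    if scale:
        aligned = [s / np.linalg.norm(s) for s in aligned]
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        new = []
        for s in aligned:
            pose, _ = solve_rigid_alignment(s, consensus)
            new.append(pose.apply(s))
        next_consensus = np.mean(new, axis=0)
        shift = float(np.max(np.abs(next_consensus - consensus)))
        aligned, consensus = new, next_consensus
        if shift < tol:
            break
    devs = np.array([rms_point_error(s, consensus) for s in aligned])
    return consensus, devs
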