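"""Multi-loop mechanism graph, mobility analysis and constrained forward
kinematics.

A mechanism is a connected graph of rigid links joined by revolute, universal,
spherical and prismatic joints, with exactly one fixed link as the reference
frame.  Compliant soft-tissue elements (ligaments, muscle) are struts: two
half-links joined by a prismatic slider with a spherical joint at each end.

Two censuses coexist:

* the *structural* census counts every half-link and every joint (what the
  solver sees);
* the *reported* census counts each strut's prismatic pair as a single link,
  attributing the sliding DoF to a composite end joint, which is the standard
  way these mechanisms are tallied in the comparative literature.

Both give the same loop count and the same Chebychev-Grübler-Kutzbach
mobility, and the numeric (constraint-Jacobian nullity) mobility agrees with
them at generic conformations.

All geometry is declared in the world frame at the *reference conformation*,
where every link frame coincides with the world frame and all joint
coordinates are zero, so loop closure holds exactly at the reference by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .core import Pose
from .joints import JointType

__all__ = [
    "Mechanism",
    "MechJoint",
    "DoFParameterization",
    "Conformation",
    "ClosureError",
    "count_loops",
    "gruebler_mobility",
    "numeric_mobility",
    "forward_kinematics",
]


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (hot path; avoids object overhead)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


class ClosureError(RuntimeError):
    """Loop-closure solve failed; carries the name of the worst loop."""

    def __init__(self, message: str, loop: str | None = None):
        super().__init__(message)
        self.loop = loop


@dataclass
class MechJoint:
    """One joint of a mechanism, declared in reference-world coordinates."""

    name: str
    parent: str
    child: str
    kind: JointType
    center: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.axes.shape != (self.kind.n_axes, 3):
            raise ValueError(f"joint {self.name}: {self.kind.value} needs "
                             f"{self.kind.n_axes} axes")
        self.axes = self.axes / np.linalg.norm(self.axes, axis=1)[:, None]

    @property
    def dof(self) -> int:
        return self.kind.dof

    def local_pose(self, q: np.ndarray) -> Pose:
        """Child-relative-to-parent pose at coordinates ``q`` (zero=identity)."""
        if self.kind is JointType.PRISMATIC:
            return Pose(np.eye(3), self.axes[0] * q[0])
        R = np.eye(3)
        for axis, angle in zip(self.axes, q):
            R = R @ _rodrigues(axis, angle)
        return Pose(R, self.center - R @ self.center)

    def partial_rotations(self, q: np.ndarray) -> list[np.ndarray]:
        """Products R(a1,q1)..R(a_{k-1},q_{k-1}) for each coordinate k."""
        out = [np.eye(3)]
        R = np.eye(3)
        for axis, angle in zip(self.axes[:-1], q[:-1]):
            R = R @ _rodrigues(axis, angle)
            out.append(R.copy())
        return out


@dataclass
class _StrutRecord:
    name: str
    body_a: str
    body_b: str
    half_a: str
    half_b: str
    joint_a: str      # spherical at anchor_a
    joint_p: str      # prismatic (length change)
    joint_b: str      # spherical at anchor_b
    rest_length: float


@dataclass
class KinematicState:
    """Poses plus per-coordinate world screw axes at a coordinate vector q."""

    q: np.ndarray
    poses: dict[str, Pose]
    omega: np.ndarray        # (nq,3) rotation axis (0 for prismatic coords)
    anchor: np.ndarray       # (nq,3) point on the axis
    tdir: np.ndarray         # (nq,3) translation direction (prismatic only)


def _complement_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (deterministic)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


class Mechanism:
    """Link/joint graph with one fixed link and loop-closure kinematics."""

    def __init__(self, name: str = "mechanism"):
        self.name = name
        self.links: list[str] = []
        self.fixed_link: str | None = None
        self.joints: list[MechJoint] = []
        self.struts: list[_StrutRecord] = []
        self._finalized = False

    # -- construction -------------------------------------------------------
    def add_link(self, name: str, fixed: bool = False) -> None:
        if name in self.links:
            raise ValueError(f"duplicate link {name!r}")
        self.links.append(name)
        if fixed:
            if self.fixed_link is not None:
                raise ValueError("exactly one fixed link allowed")
            self.fixed_link = name

    def add_joint(self, name: str, parent: str, child: str,
                  kind: JointType | str, center, axes) -> None:
        kind = JointType(kind) if not isinstance(kind, JointType) else kind
        if parent == child:
            raise ValueError(f"joint {name!r} must join two distinct links")
        for ln in (parent, child):
            if ln not in self.links:
                raise ValueError(f"joint {name!r}: unknown link {ln!r}")
        if any(j.name == name for j in self.joints):
            raise ValueError(f"duplicate joint {name!r}")
        self.joints.append(MechJoint(name, parent, child, kind,
                                     np.asarray(center, float),
                                     np.asarray(axes, float)))
        self._finalized = False

    def add_strut(self, name: str, body_a: str, anchor_a, body_b: str,
                  anchor_b) -> None:
        """Add a spherical-prismatic-spherical soft-tissue strut.

        The first spherical joint's third axis is the strut axis, so its
        third coordinate is the strut's long-axis spin; the prismatic
        coordinate is the length change from rest (mm).
        """
        anchor_a = np.asarray(anchor_a, dtype=float).reshape(3)
        anchor_b = np.asarray(anchor_b, dtype=float).reshape(3)
        u = anchor_b - anchor_a
        rest = float(np.linalg.norm(u))
        if rest <= 0:
            raise ValueError("strut anchors coincide")
        u = u / rest
        e1, e2 = _complement_basis(u)
        half_a, half_b = f"{name}__a", f"{name}__b"
        self.add_link(half_a)
        self.add_link(half_b)
        self.add_joint(f"{name}__ball_a", body_a, half_a, JointType.SPHERICAL,
                       anchor_a, np.array([e1, e2, u]))
        self.add_joint(f"{name}__slide", half_a, half_b, JointType.PRISMATIC,
                       anchor_a, np.array([u]))
        self.add_joint(f"{name}__ball_b", half_b, body_b, JointType.SPHERICAL,
                       anchor_b, np.array([e1, e2, u]))
        self.struts.append(_StrutRecord(name, body_a, body_b, half_a, half_b,
                                        f"{name}__ball_a", f"{name}__slide",
                                        f"{name}__ball_b", rest))
        self._finalized = False

    def joint(self, name: str) -> MechJoint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    # -- topology -----------------------------------------------------------
    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.links)
        for j in self.joints:
            g.add_edge(j.parent, j.child, key=j.name)
        return g

    def finalize(self) -> "Mechanism":
        """Validate connectivity, lay out coordinates, build the spanning tree."""
        if self.fixed_link is None:
            raise ValueError("no fixed link declared")
        g = self.graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError("mechanism graph is disconnected")
        # coordinate layout
        self.coord_slices: dict[str, slice] = {}
        off = 0
        for j in self.joints:
            self.coord_slices[j.name] = slice(off, off + j.dof)
            off += j.dof
        self.nq = off
        # spanning tree: scan joints in declaration order, attach any joint
        # with exactly one visited endpoint; repeat until no growth
        visited = {self.fixed_link}
        self.tree: list[tuple[str, str, bool]] = []  # (link, joint, forward)
        used: set[str] = set()
        grew = True
        while grew:
            grew = False
            for j in self.joints:
                if j.name in used:
                    continue
                pin, cin = j.parent in visited, j.child in visited
                if pin and not cin:
                    visited.add(j.child)
                    self.tree.append((j.child, j.name, True))
                    used.add(j.name)
                    grew = True
                elif cin and not pin:
                    visited.add(j.parent)
                    self.tree.append((j.parent, j.name, False))
                    used.add(j.name)
                    grew = True
        self.chords: list[str] = [j.name for j in self.joints
                                  if j.name not in used]
        # moving-set bools: moves[i, l] == coordinate i moves link l
        nl = len(self.links)
        self._lidx = {l: i for i, l in enumerate(self.links)}
        moves = np.zeros((self.nq, nl), dtype=bool)
        # subtree membership: walk tree edges; removing a tree edge splits
        # the tree; the far-side component moves under that edge's coords
        children: dict[str, list[str]] = {l: [] for l in self.links}
        for link, jn, _fw in self.tree:
            j = self.joint(jn)
            other = j.parent if link == j.child else j.child
            children[other].append(link)
        def subtree(link):
            out, stack = [], [link]
            while stack:
                x = stack.pop()
                out.append(x)
                stack.extend(children[x])
            return out
        for link, jn, fw in self.tree:
            sl = self.coord_slices[jn]
            for m in subtree(link):
                moves[sl, self._lidx[m]] = True
        self._moves = moves
        self._tree_edge_sign = {jn: (1.0 if fw else -1.0)
                                for _, jn, fw in self.tree}
        self._finalized = True
        return self

    def _require_finalized(self):
        if not self._finalized:
            self.finalize()

    # -- censuses -----------------------------------------------------------
    def structural_counts(self) -> dict[str, int]:
        self._require_finalized()
        n, j = len(self.links), len(self.joints)
        f = sum(jt.dof for jt in self.joints)
        return {"links": n, "joints": j, "joint_dof_sum": f,
                "loops": j - n + 1, "mobility": 6 * (n - 1 - j) + f}

    def census_counts(self) -> dict[str, int]:
        """Reported census: each strut's prismatic pair counts as one link
        (its sliding DoF rides on a composite end joint), so each strut drops
        one link and one joint relative to the structural census while the
        summed joint DoFs are unchanged.  Loop count and mobility are
        invariant under this merge."""
        s = self.structural_counts()
        k = len(self.struts)
        n, j, f = s["links"] - k, s["joints"] - k, s["joint_dof_sum"]
        return {"links": n, "joints": j, "joint_dof_sum": f,
                "loops": j - n + 1, "mobility": 6 * (n - 1 - j) + f}

    # -- kinematics ---------------------------------------------------------
    def zero_q(self) -> np.ndarray:
        self._require_finalized()
        return np.zeros(self.nq)

    def evaluate(self, q: np.ndarray) -> KinematicState:
        """Forward pass: link poses and world screw axes at coordinates q."""
        self._require_finalized()
        q = np.asarray(q, dtype=float)
        poses: dict[str, Pose] = {self.fixed_link: Pose.identity()}
        for link, jn, fw in self.tree:
            j = self.joint(jn)
            T = j.local_pose(q[self.coord_slices[jn]])
            if fw:
                poses[link] = poses[j.parent] @ T
            else:
                poses[link] = poses[j.child] @ T.inverse()
        omega = np.zeros((self.nq, 3))
        anchor = np.zeros((self.nq, 3))
        tdir = np.zeros((self.nq, 3))
        for j in self.joints:
            sl = self.coord_slices[j.name]
            pp = poses[j.parent]
            if j.kind is JointType.PRISMATIC:
                tdir[sl.start] = pp.rotation @ j.axes[0]
                continue
            qj = q[sl]
            partials = j.partial_rotations(qj)
            cw = pp.apply(j.center)
            for k in range(j.dof):
                omega[sl.start + k] = pp.rotation @ (partials[k] @ j.axes[k])
                anchor[sl.start + k] = cw
        return KinematicState(q=q, poses=poses, omega=omega, anchor=anchor,
                              tdir=tdir)

    def closure_residual(self, state: KinematicState,
                         with_jacobian: bool = True,
                         ) -> tuple[np.ndarray, np.ndarray | None]:
        """Stacked 6-vector loop residuals over chord joints (+ Jacobian).

        Per chord: rotation residual as an axis-angle vector (rad, expressed
        in the chord child's frame, which makes it invariant to common-mode
        motion of the two loop branches) and translation residual in mm
        between the chord-predicted child pose and the tree-computed child
        pose.  The Jacobian columns come from the world screw axes of the
        coordinates, signed by which side of the loop each coordinate moves;
        it is exact in translation and accurate to second order in the
        rotation residual.
        """
        nq = self.nq
        res = np.zeros(6 * len(self.chords))
        J = np.zeros((6 * len(self.chords), nq)) if with_jacobian else None
        for li, cn in enumerate(self.chords):
            j = self.joint(cn)
            sl = self.coord_slices[cn]
            T = j.local_pose(state.q[sl])
            A = state.poses[j.parent] @ T
            B = state.poses[j.child]
            r_rot = Rotation.from_matrix(
                B.rotation.T @ A.rotation).as_rotvec()
            r_tr = A.translation - B.translation
            res[6 * li: 6 * li + 3] = r_rot
            res[6 * li + 3: 6 * li + 6] = r_tr
            if not with_jacobian:
                continue
            mP = self._moves[:, self._lidx[j.parent]].astype(float)
            mQ = self._moves[:, self._lidx[j.child]].astype(float)
            tA, tB = A.translation, B.translation
            Jrot_w = (mP - mQ)[:, None] * state.omega
            Jtr = (mP[:, None] * np.cross(state.omega, tA - state.anchor)
                   - mQ[:, None] * np.cross(state.omega, tB - state.anchor)
                   + (mP - mQ)[:, None] * state.tdir)
            # chord's own coordinates act on the predicted pose (P side)
            pp = state.poses[j.parent]
            if j.kind is JointType.PRISMATIC:
                Jtr[sl.start] += pp.rotation @ j.axes[0]
            else:
                partials = j.partial_rotations(state.q[sl])
                cw = pp.apply(j.center)
                for k in range(j.dof):
                    w = pp.rotation @ (partials[k] @ j.axes[k])
                    Jrot_w[sl.start + k] += w
                    Jtr[sl.start + k] += np.cross(w, tA - cw)
            # body-frame rotvec derivative: rotate the differential angular
            # velocity into the child frame, then apply the first-order
            # inverse-log-map correction  dr = w_b - (r x w_b)/2
            Jrot = Jrot_w @ B.rotation
            Jrot = Jrot + 0.5 * np.cross(Jrot, r_rot[None, :])
            J[6 * li: 6 * li + 3] = Jrot.T
            J[6 * li + 3: 6 * li + 6] = Jtr.T
        return res, J

    def solve_closure(self, q0: np.ndarray, pin_matrix: np.ndarray,
                      pin_rhs: np.ndarray, tol: float = 1e-10,
                      max_iter: int = 60) -> np.ndarray:
        """Damped Newton on [loop residuals; linear pins] from q0.

        The step solves the stacked linear system in the least-squares sense,
        which transparently handles overconstrained (redundant) loops such as
        a planar four-bar described with the spatial formulation.
        """
        q = np.asarray(q0, dtype=float).copy()
        pin_matrix = np.atleast_2d(pin_matrix)

        def full_res(qv):
            st = self.evaluate(qv)
            r, J = self.closure_residual(st)
            rr = np.concatenate([r, pin_matrix @ qv - pin_rhs])
            JJ = np.vstack([J, pin_matrix])
            return rr, JJ

        rr, JJ = full_res(q)
        for _ in range(max_iter):
            if np.max(np.abs(rr)) < tol:
                return q
            dq = np.linalg.lstsq(JJ, -rr, rcond=None)[0]
            # trust-region cap: rotations move at most ~0.5 rad per step
            cap = float(np.max(np.abs(dq)))
            if cap > 0.5:
                dq *= 0.5 / cap
            step = 1.0
            base = np.linalg.norm(rr)
            for _ in range(12):
                q_try = q + step * dq
                rr_try, JJ_try = full_res(q_try)
                if np.linalg.norm(rr_try) < base * (1 - 1e-4 * step) or \
                        np.linalg.norm(rr_try) < tol:
                    q, rr, JJ = q_try, rr_try, JJ_try
                    break
                step *= 0.5
            else:
                break
        if np.max(np.abs(rr)) >= tol:
            worst = int(np.argmax([np.max(np.abs(rr[6 * i:6 * i + 6]))
                                   for i in range(len(self.chords))]))
            raise ClosureError(
                f"loop closure failed (|res|={np.max(np.abs(rr)):.3e}), "
                f"worst loop at chord joint {self.chords[worst]!r}",
                loop=self.chords[worst])
        return q


@dataclass
class DoFParameterization:
    """Labeled scalar input parameters of a mechanism.

    Parameters are linear functions of the joint coordinates:
    ``p = matrix @ q + offset`` (symmetric/antisymmetric combinations of
    paired joints, raw joint angles, or strut lengths — the offset carries
    rest lengths).  The number of parameters equals the mechanism's mobility.
    ``freeze_mask``/``freeze_values`` record which parameters are currently
    held at fixed values (by convention their trajectory means).
    """

    mechanism: Mechanism
    labels: list[str]
    matrix: np.ndarray
    offset: np.ndarray
    groups: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    freeze_mask: dict[str, bool] = field(default_factory=dict)
    freeze_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float).reshape(-1)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("parameter labels must be unique")
        if self.matrix.shape != (n, self.mechanism.nq):
            raise ValueError("parameter matrix shape mismatch")
        if self.offset.shape != (n,):
            raise ValueError("offset shape mismatch")
        mob = self.mechanism.census_counts()["mobility"]
        if n != mob:
            # the counting formula is misled by overconstrained (e.g.
            # planar-in-spatial) topologies; fall back to the rank oracle
            true_mob = numeric_mobility(self.mechanism)
            if n != true_mob:
                raise ValueError(f"{n} parameters != mechanism mobility "
                                 f"{mob} (formula) / {true_mob} (numeric)")
        for lab in self.labels:
            self.freeze_mask.setdefault(lab, False)
            self.freeze_values.setdefault(lab, 0.0)

    @property
    def n_params(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def params_of(self, q: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(q, float) + self.offset

    def param_dict(self, q: np.ndarray) -> dict[str, float]:
        vals = self.params_of(q)
        return {lab: float(v) for lab, v in zip(self.labels, vals)}

    def pin_system(self, values: dict[str, float] | np.ndarray,
                   labels: list[str] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Rows (M, rhs) pinning the given parameters: M q = rhs."""
        if labels is None:
            labels = list(self.labels)
        if isinstance(values, dict):
            vals = np.array([values[lab] for lab in labels], dtype=float)
        else:
            vals = np.asarray(values, dtype=float)
        idx = [self.index(lab) for lab in labels]
        return self.matrix[idx], vals - self.offset[idx]

    def reference_values(self) -> dict[str, float]:
        return self.param_dict(self.mechanism.zero_q())


@dataclass
class Conformation:
    """A loop-consistent pose of every link plus the parameter values."""

    q: np.ndarray
    poses: dict[str, Pose]
    params: dict[str, float]
    closure_residual: float


def count_loops(mech: Mechanism) -> int:
    """Independent closed loops: joints - links + 1 on a connected graph.

    Identical for the structural and the reported census, and equal to the
    dimension of the graph's cycle space.
    """
    g = mech.graph()
    if not nx.is_connected(g):
        raise ValueError("mechanism graph is disconnected")
    return mech.census_counts()["loops"]


def gruebler_mobility(mech: Mechanism) -> int:
    """Chebychev-Grübler-Kutzbach spatial mobility: 6(n-1-j) + sum(f_i)."""
    return mech.census_counts()["mobility"]


def numeric_mobility(mech: Mechanism, q: np.ndarray | None = None,
                     rel_tol: float = 1e-8) -> int:
    """Mobility as the nullity of the loop-closure Jacobian at q.

    Independent of any counting convention, so it serves as an oracle for
    the Chebychev-Grübler-Kutzbach formula and flags overconstrained
    (e.g., planar-in-spatial) or singular conformations where they disagree.
    Requires q to satisfy closure.
    """
    mech._require_finalized()
    if q is None:
        q = mech.zero_q()
    st = mech.evaluate(q)
    r, J = mech.closure_residual(st)
    if len(r) and np.max(np.abs(r)) > 1e-6:
        raise ValueError("conformation does not satisfy loop closure")
    if J is None or J.size == 0:
        return mech.nq
    s = np.linalg.svd(J, compute_uv=False)
    rank = int(np.sum(s > rel_tol * s[0])) if s[0] > 0 else 0
    return mech.nq - rank


def forward_kinematics(mech: Mechanism, par: DoFParameterization,
                       params: dict[str, float] | np.ndarray,
                       init: Conformation | np.ndarray | None = None,
                       free_labels: tuple[str, ...] = (),
                       tol: float = 1e-10, max_iter: int = 60,
                       min_step: float = 1.0 / 256.0) -> Conformation:
    """Pose the mechanism at the given input parameters.

    Solves the loop-closure constraints for the dependent joint coordinates
    by damped Newton, warm-started from ``init`` (the reference conformation
    by default), so the assembly branch is selected by continuation.

    Parameters named in ``free_labels`` are not pinned: they settle to
    whatever value closure requires (minimal-norm continuation from the warm
    start).  This is how compliant soft-tissue lengths are allowed to follow
    the skeletal motion instead of being driven.
    """
    if isinstance(params, dict):
        vals = np.array([params.get(lab, 0.0) for lab in par.labels],
                        dtype=float)
    else:
        vals = np.asarray(params, dtype=float)
    if init is None:
        q0 = mech.zero_q()
    elif isinstance(init, Conformation):
        q0 = init.q.copy()
    else:
        q0 = np.asarray(init, dtype=float).copy()
    # continuation along the straight parameter path from the warm start:
    # take the full step; if Newton fails, bisect the remaining step.  This
    # keeps the solution on the assembly branch of the warm start.
    pinned = [lab for lab in par.labels if lab not in free_labels]
    start_vals = par.params_of(q0)
    q, lam, step = q0, 0.0, 1.0
    while lam < 1.0:
        target = start_vals + min(lam + step, 1.0) * (vals - start_vals)
        M, rhs = par.pin_system(
            {lab: target[par.index(lab)] for lab in pinned}, pinned)
        try:
            q_new = mech.solve_closure(q, M, rhs, tol=tol, max_iter=max_iter)
        except ClosureError:
            step *= 0.5
            if step < min_step:
                raise
            continue
        q = q_new
        lam = min(lam + step, 1.0)
        step = min(step * 2.0, 1.0 - lam if lam < 1.0 else 1.0)
        step = max(step, 1e-9)
    st = mech.evaluate(q)
    r, _ = mech.closure_residual(st, with_jacobian=False)
    return Conformation(q=q, poses=st.poses, params=par.param_dict(q),
                        closure_residual=float(np.max(np.abs(r))) if len(r)
                        else 0.0)
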