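"""Shared fixtures: the catfish mechanism, small benchmark linkages, and the
closed-form planar four-bar oracle."""
import numpy as np
import pytest

from skullkin.joints import JointType
from skullkin.mechanism import DoFParameterization, Mechanism


@pytest.fixture(scope="session")
def catfish():
    """(mechanism, parameterization, fit point sets) - built once."""
    from skullkin.fixture import build_catfish_fixture
    return build_catfish_fixture()


@pytest.fixture(scope="session")
def kdof_scan(catfish):
    """A freeze scan over noise-free motion generated by three rotational
    inputs with effect-ordered amplitudes (K > I > J), G and H inert, and
    the compliant soft-tissue lengths following the skeleton (so A and B
    vary too, while L varies but is invisible to left-side scoring).

    The scan starts from the eight-label measurable set {A,B,L,I,J,K,G,H}
    with freeze values equal to the true trajectory means, four frames,
    errors scored on the five unilateral elements, and the mean statistic
    (localized single-element effects would vanish in the median of a
    15-point distribution).  Returns (curve, truth).
    """
    from skullkin.fitting import sequential_freeze, targets_from_poses
    from skullkin.fixture import ERROR_BODIES
    from skullkin.mechanism import forward_kinematics

    mech, par, fps = catfish
    amps = {"I": 0.25, "J": 0.02, "K": 0.30}
    frames, true_params, qs = [], [], []
    conf = None
    for ph in np.linspace(0.3, 1.0, 4):
        vals = par.reference_values()
        vals.update({k: a * ph for k, a in amps.items()})
        conf = forward_kinematics(mech, par, vals, init=conf,
                                  free_labels=("A", "B", "L"))
        true_params.append(conf.params)
        qs.append(conf.q.copy())
        frames.append(targets_from_poses(conf.poses, fps,
                                         list(ERROR_BODIES)))
    means = {lab: float(np.mean([p[lab] for p in true_params]))
             for lab in par.labels}
    start = ["A", "B", "L", "I", "J", "K", "G", "H"]
    curve = sequential_freeze(mech, par, frames, fps, start, means,
                              head_length=76.0, statistic="mean",
                              fit_max_nfev=300, fit_xtol=1e-12,
                              q_inits=qs)
    return curve, {"amps": amps, "means": means, "n_frames": len(frames),
                   "true_params": true_params}


# -- planar four-bar ---------------------------------------------------------
# ground pivots O1=(0,0,0), O2=(10,0,0); crank 2, coupler 9, rocker 5.
FOURBAR_O1 = np.zeros(3)
FOURBAR_O2 = np.array([10.0, 0.0, 0.0])
FOURBAR_A0 = np.array([2.0, 0.0, 0.0])
FOURBAR_B0 = np.array([9.5, np.sqrt(24.75), 0.0])
_Z = np.array([[0.0, 0.0, 1.0]])


def make_fourbar() -> tuple[Mechanism, DoFParameterization]:
    m = Mechanism("fourbar")
    m.add_link("ground", fixed=True)
    for l in ("crank", "coupler", "rocker"):
        m.add_link(l)
    m.add_joint("o1", "ground", "crank", JointType.REVOLUTE, FOURBAR_O1, _Z)
    m.add_joint("a", "crank", "coupler", JointType.REVOLUTE, FOURBAR_A0, _Z)
    m.add_joint("b", "coupler", "rocker", JointType.REVOLUTE, FOURBAR_B0, _Z)
    m.add_joint("o2", "rocker", "ground", JointType.REVOLUTE, FOURBAR_O2, _Z)
    m.finalize()
    M = np.zeros((1, m.nq))
    M[0, m.coord_slices["o1"].start] = 1.0
    par = DoFParameterization(mechanism=m, labels=["theta"], matrix=M,
                              offset=np.zeros(1))
    return m, par


def fourbar_closed_form(thetas):
    """Coupler-tip (joint B) positions from the two-circle intersection,
    branch selected by continuity from the reference assembly."""
    out = []
    prev = FOURBAR_B0[:2]
    for th in np.atleast_1d(thetas):
        A = 2.0 * np.array([np.cos(th), np.sin(th)])
        d2 = FOURBAR_O2[:2] - A
        d = np.linalg.norm(d2)
        a = (d * d + 81.0 - 25.0) / (2.0 * d)
        h2 = 81.0 - a * a
        if h2 < 0:
            raise ValueError("four-bar cannot assemble at this crank angle")
        h = np.sqrt(h2)
        u = d2 / d
        perp = np.array([-u[1], u[0]])
        cands = [A + a * u + h * perp, A + a * u - h * perp]
        B = min(cands, key=lambda c: np.linalg.norm(c - prev))
        prev = B
        out.append([B[0], B[1], 0.0])
    return np.asarray(out)


def make_rssr() -> Mechanism:
    """Spatial RSSR four-bar with skew revolute axes (generic geometry)."""
    m = Mechanism("rssr")
    m.add_link("ground", fixed=True)
    for l in ("crank", "coupler", "rocker"):
        m.add_link(l)
    m.add_joint("r1", "ground", "crank", JointType.REVOLUTE,
                [0.0, 0.0, 0.0], [[0.2, 0.3, 0.93]])
    m.add_joint("s1", "crank", "coupler", JointType.SPHERICAL,
                [3.0, 1.0, 0.5], np.eye(3))
    m.add_joint("s2", "coupler", "rocker", JointType.SPHERICAL,
                [7.0, 4.0, 2.0], np.eye(3))
    m.add_joint("r2", "rocker", "ground", JointType.REVOLUTE,
                [10.0, 1.0, 0.0], [[0.7, -0.2, 0.69]])
    return m.finalize()


def make_rigid_triangle() -> Mechanism:
    """Three links in a ring with skew revolute axes: a rigid structure."""
    m = Mechanism("triangle")
    m.add_link("a", fixed=True)
    m.add_link("b")
    m.add_link("c")
    m.add_joint("j1", "a", "b", JointType.REVOLUTE,
                [0.0, 0.0, 0.0], [[0.9, 0.1, 0.42]])
    m.add_joint("j2", "b", "c", JointType.REVOLUTE,
                [4.0, 2.0, 1.0], [[-0.2, 0.9, 0.39]])
    m.add_joint("j3", "c", "a", JointType.REVOLUTE,
                [1.0, 5.0, -1.0], [[0.3, -0.4, 0.87]])
    return m.finalize()


def make_random_ring(rng: np.random.Generator, n_links=None) -> Mechanism:
    """A random single-loop spatial mechanism with summed joint DoFs >= 7."""
    kinds = [JointType.REVOLUTE, JointType.UNIVERSAL, JointType.SPHERICAL,
             JointType.PRISMATIC]
    while True:
        n = int(n_links or rng.integers(4, 8))
        choice = [kinds[i] for i in rng.integers(0, len(kinds), size=n)]
        if sum(k.dof for k in choice) >= 7:
            break
    m = Mechanism("ring")
    names = [f"l{i}" for i in range(n)]
    m.add_link(names[0], fixed=True)
    for nm in names[1:]:
        m.add_link(nm)
    for i, kind in enumerate(choice):
        axes = rng.normal(size=(kind.n_axes, 3))
        if kind is JointType.SPHERICAL:
            # orthonormal triad so the spherical coordinates behave
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            axes = q.T
        m.add_joint(f"j{i}", names[i], names[(i + 1) % n], kind,
                    rng.uniform(-10, 10, size=3), axes)
    return m.finalize()
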