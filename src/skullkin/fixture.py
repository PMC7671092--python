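"""The catfish-skull fixture: a five-loop cranial linkage with 19 labeled DoFs.

The fixture assembles the mandibular arch, hyoid arch and pectoral girdle of
a channel-catfish-like skull as a parallel mechanism:

* 14 skeletal elements — neurocranium (fixed), urohyal, and left/right
  suspensorium, mandible, operculum, hyoid, post-temporal, cleithrum;
* 3 soft-tissue struts — the left and right interoperculomandibular (IOM)
  ligaments (operculum to mandible) and the sternohyoideus muscle (urohyal to
  cleithrum), each a spherical-prismatic-spherical chain.

Reported census: 17 links (each strut's prismatic pair counted as one link),
21 joints with summed joint DoFs 49, five independent loops, and
Chebychev-Grübler-Kutzbach mobility 19.

Joint types (the literature does not print a per-articulation table, so the
assignment below is this fixture's single source of truth; any alternative
may be supplied through the geometry config provided the census invariants
still hold):

====================================  =========  ====
articulation                          type       DoF
====================================  =========  ====
neurocranium-suspensorium (L, R)      revolute   1
suspensorium-mandible (L, R)          universal  2
suspensorium-operculum (L, R)         universal  2
suspensorium-hyoid / interhyal (L,R)  spherical  3
hyoid-urohyal (L, R)                  spherical  3
neurocranium-post-temporal (L, R)     revolute   1
post-temporal-cleithrum (L, R)        revolute   1
cleithrum-cleithrum (midline)         universal  2
====================================  =========  ====

The girdle loop (neurocranium - post-temporals - cleithra) sums to exactly
six joint DoFs, so the pectoral girdle is a rigid frame at generic
conformations — consistent with the heavily sutured catfish girdle and with
the absence of girdle rotations among the 19 labeled parameters.

Parameter labels A-S (grouping 3 lengths + 4 asymmetric midline + 4
opercular + mandibular/suspensorial/hyoid depression + 5 long-axis spins):

A  left IOM ligament length (mm)      L  right IOM ligament length (mm)
B  sternohyoideus length (mm)         M  right opercular abduction (rad)
C  asymmetric mandibular depression   N  right opercular flaring out (rad)
D  asymmetric hyoid depression        O  left hyoid long-axis spin (rad)
E  urohyal yaw                        P  right hyoid long-axis spin (rad)
F  asymmetric suspensorial abduction  Q  left IOM spin (rad)
G  left opercular abduction (rad)     R  right IOM spin (rad)
H  left opercular flaring out (rad)   S  sternohyoideus spin (rad)
I  mandibular depression (rad)
J  suspensorial abduction (rad)
K  hyoid depression (rad)

The hyoids are the two non-strut links with spherical joints at both ends,
carrying the two skeletal long-axis spins (O, P); struts carry Q, R, S.

Anatomical frame: +x rostral->caudal, +y left->right (left side at y < 0),
+z ventral->dorsal, origin at the rostral tip of the neurocranium; mm.
Right-side geometry mirrors the left through the midsagittal plane y = 0;
mirrored rotation axes are stored sign-flipped so that equal left/right
coordinate values produce bilaterally symmetric motion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import FitPointSet
from .joints import JointType
from .mechanism import DoFParameterization, Mechanism, numeric_mobility

__all__ = ["CatfishGeometry", "build_catfish_fixture", "mirror_point",
           "mirror_axis", "PRIMARY_DOFS", "APRIORI_FROZEN", "MARKED_BODIES",
           "ERROR_BODIES"]

#: The five DoFs that carry most feeding motion (left side).
PRIMARY_DOFS = ("I", "J", "K", "G", "H")

#: DoFs not measurable from unilateral bone markers: the five long-axis
#: spins plus the three right-side-only parameters.
APRIORI_FROZEN = ("L", "M", "N", "O", "P", "Q", "R", "S")

#: Elements carrying markers in a unilateral marking scheme.
MARKED_BODIES = ("neurocranium", "urohyal", "posttemporal_L", "cleithrum_L",
                 "suspensorium_L", "operculum_L", "mandible_L", "hyoid_L")

#: Mobile elements on which model-fit error is scored (3 fit points each).
ERROR_BODIES = ("suspensorium_L", "operculum_L", "mandible_L", "hyoid_L",
                "urohyal")


def mirror_point(p) -> np.ndarray:
    """Reflect a point through the midsagittal plane (y -> -y)."""
    return np.asarray(p, dtype=float) * np.array([1.0, -1.0, 1.0])


def mirror_axis(a) -> np.ndarray:
    """Reflect a rotation axis and flip its sign, so that equal coordinate
    values on mirrored joints generate mirror-symmetric motion."""
    return -mirror_point(a)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class CatfishGeometry:
    """Left-side joint centers/axes and strut anchors (mm, reference pose).

    The default numbers describe a head of ~76 mm length.  ``scale``
    multiplies all positions isotropically; ``jitter_mm``/``seed`` add
    individual variation to joint centers and anchors (used by the synthetic
    individual generator).  Axes are unit-normalized on build.
    """

    head_length: float = 76.0
    scale: float = 1.0
    jitter_mm: float = 0.0
    seed: int | None = None

    # axis signs chosen so positive coordinates act in the documented
    # anatomical sense (depression, abduction, flaring out) on the left side
    susp_center: tuple = (30.0, -13.0, 6.0)
    susp_axis: tuple = (-0.92, 0.10, -0.38)
    jaw_center: tuple = (44.0, -18.0, -7.0)
    jaw_axes: tuple = ((0.15, -0.97, 0.10), (0.93, 0.20, 0.30))
    opercular_center: tuple = (48.0, -16.0, 3.0)
    opercular_axes: tuple = ((-0.20, 0.25, -0.95), (-0.90, 0.22, 0.33))
    interhyal_center: tuple = (46.0, -13.0, -11.0)
    hyoid_urohyal_center: tuple = (27.0, -2.5, -15.0)
    posttemporal_center: tuple = (58.0, -10.0, 9.0)
    posttemporal_axis: tuple = (0.30, -0.90, 0.31)
    cleithral_center: tuple = (63.0, -12.0, 1.0)
    cleithral_axis: tuple = (-0.20, -0.83, 0.52)
    girdle_center: tuple = (70.0, 0.0, -13.0)
    # oblique axes: with both axes in the midsagittal plane the girdle
    # loop is structurally rank-deficient (its symmetric constraint block
    # loses a direction), so the axes carry out-of-plane components
    girdle_axes: tuple = ((0.80, 0.35, 0.49), (0.15, -0.50, -0.85))
    iom_opercular_anchor: tuple = (50.0, -18.0, -6.0)
    iom_mandible_anchor: tuple = (40.0, -17.0, -12.0)
    sh_urohyal_anchor: tuple = (25.0, 0.0, -17.0)
    sh_cleithral_anchor: tuple = (68.0, -3.0, -16.0)

    # three landmarks per body, spread across the element (body frame = world
    # frame at reference)
    fit_points: dict = field(default_factory=lambda: {
        "neurocranium": [(5.0, 0.0, 8.0), (40.0, -8.0, 14.0), (40.0, 8.0, 14.0)],
        "suspensorium_L": [(32.0, -14.0, 4.0), (45.0, -17.5, -5.0),
                           (47.0, -14.5, 0.0)],
        "mandible_L": [(42.0, -17.5, -8.0), (24.0, -12.0, -11.0),
                       (10.0, -4.0, -10.0)],
        "operculum_L": [(49.0, -16.5, 1.5), (57.0, -20.5, -4.0),
                        (52.0, -18.5, -9.5)],
        "hyoid_L": [(44.0, -12.0, -11.5), (36.0, -8.0, -13.5),
                    (29.0, -3.5, -14.5)],
        "urohyal": [(26.0, -1.0, -15.5), (22.0, 0.0, -16.5),
                    (26.0, 1.0, -15.5)],
        "posttemporal_L": [(57.0, -10.5, 8.0), (60.0, -11.0, 5.0),
                           (61.5, -12.5, 8.5)],
        "cleithrum_L": [(64.0, -11.5, 0.0), (67.0, -7.0, -10.0),
                        (69.0, -2.0, -14.0)],
    })

    def _jittered(self, p, rng) -> np.ndarray:
        p = np.asarray(p, dtype=float) * self.scale
        if rng is not None and self.jitter_mm > 0:
            p = p + rng.normal(0.0, self.jitter_mm, size=3)
        return p


_LABELS = list("ABCDEFGHIJKLMNOPQRS")

_GROUPS = {
    "lengths": ["A", "B", "L"],
    "asymmetric_midline": ["C", "D", "E", "F"],
    "opercular": ["G", "H", "M", "N"],
    "mandibular_depression": ["I"],
    "suspensorial_abduction": ["J"],
    "hyoid_depression": ["K"],
    "spins": ["O", "P", "Q", "R", "S"],
}

_DESCRIPTIONS = {
    "A": "left interoperculomandibular ligament length (mm)",
    "B": "sternohyoideus length (mm)",
    "C": "asymmetric mandibular depression (rad)",
    "D": "asymmetric hyoid depression (rad)",
    "E": "urohyal yaw (rad)",
    "F": "asymmetric suspensorial abduction (rad)",
    "G": "left opercular abduction (rad)",
    "H": "left opercular flaring out (rad)",
    "I": "mandibular depression (rad)",
    "J": "suspensorial abduction (rad)",
    "K": "hyoid depression (rad)",
    "L": "right interoperculomandibular ligament length (mm)",
    "M": "right opercular abduction (rad)",
    "N": "right opercular flaring out (rad)",
    "O": "left hyoid long-axis spin (rad)",
    "P": "right hyoid long-axis spin (rad)",
    "Q": "left IOM ligament long-axis spin (rad)",
    "R": "right IOM ligament long-axis spin (rad)",
    "S": "sternohyoideus long-axis spin (rad)",
}


def _interhyal_axes(center, distal) -> np.ndarray:
    """Spherical-joint axes for a hyoid bar: [depression axis, sweep axis,
    bar axis]; the bar (third) axis makes the third coordinate the spin."""
    e3 = _unit(np.asarray(distal) - np.asarray(center))
    e1 = _unit(np.cross(np.array([0.0, 0.0, 1.0]), e3))
    e2 = np.cross(e3, e1)
    return np.array([e1, e2, e3])


def build_catfish_fixture(geometry: CatfishGeometry | None = None,
                          seed: int | None = None, validate: bool = True,
                          ) -> tuple[Mechanism, DoFParameterization,
                                     dict[str, FitPointSet]]:
    """Build the five-loop catfish skull mechanism and its parameterization.

    Returns ``(mechanism, parameterization, fit_points)``.  With
    ``validate=True`` (default) the build is refused unless the census totals
    (17 links, 21 joints, sum of joint DoFs 49, 5 loops, mobility 19) hold,
    the reference conformation closes all loops, the numeric mobility equals
    the formula mobility, and the 19 parameter pins are independent of the
    loop constraints (nonsingular input map).
    """
    g = geometry or CatfishGeometry()
    rng = np.random.default_rng(seed if seed is not None else g.seed) \
        if (g.jitter_mm > 0) else None

    def P(p):
        return g._jittered(p, rng)

    m = Mechanism("catfish_skull")
    m.add_link("neurocranium", fixed=True)
    for side in ("L", "R"):
        for base in ("suspensorium", "mandible", "operculum", "hyoid",
                     "posttemporal", "cleithrum"):
            m.add_link(f"{base}_{side}")
    m.add_link("urohyal")

    # left-side geometry; right side is its midsagittal mirror
    susp_c = P(g.susp_center)
    jaw_c = P(g.jaw_center)
    op_c = P(g.opercular_center)
    ih_c = P(g.interhyal_center)
    hu_c = P(g.hyoid_urohyal_center)
    pt_c = P(g.posttemporal_center)
    cl_c = P(g.cleithral_center)
    gi_c = P(g.girdle_center)
    gi_c[1] = 0.0  # the midline joint stays on the midsagittal plane
    iom_a = P(g.iom_opercular_anchor)
    iom_b = P(g.iom_mandible_anchor)
    sh_a = P(g.sh_urohyal_anchor)
    sh_b = P(g.sh_cleithral_anchor)

    susp_ax = _unit(g.susp_axis)
    jaw_ax = np.array([_unit(a) for a in g.jaw_axes])
    op_ax = np.array([_unit(a) for a in g.opercular_axes])
    pt_ax = _unit(g.posttemporal_axis)
    cl_ax = _unit(g.cleithral_axis)
    gi_ax = np.array([_unit(a) for a in g.girdle_axes])
    ih_ax = _interhyal_axes(ih_c, hu_c)
    hu_ax = _interhyal_axes(hu_c, ih_c)

    def mirrored(axes):
        return np.array([mirror_axis(a) for a in np.atleast_2d(axes)])

    m.add_joint("susp_cranial_L", "neurocranium", "suspensorium_L",
                JointType.REVOLUTE, susp_c, [susp_ax])
    m.add_joint("susp_cranial_R", "neurocranium", "suspensorium_R",
                JointType.REVOLUTE, mirror_point(susp_c), mirrored(susp_ax))
    m.add_joint("jaw_L", "suspensorium_L", "mandible_L",
                JointType.UNIVERSAL, jaw_c, jaw_ax)
    m.add_joint("jaw_R", "suspensorium_R", "mandible_R",
                JointType.UNIVERSAL, mirror_point(jaw_c), mirrored(jaw_ax))
    m.add_joint("opercular_L", "suspensorium_L", "operculum_L",
                JointType.UNIVERSAL, op_c, op_ax)
    m.add_joint("opercular_R", "suspensorium_R", "operculum_R",
                JointType.UNIVERSAL, mirror_point(op_c), mirrored(op_ax))
    m.add_joint("interhyal_L", "suspensorium_L", "hyoid_L",
                JointType.SPHERICAL, ih_c, ih_ax)
    m.add_joint("interhyal_R", "suspensorium_R", "hyoid_R",
                JointType.SPHERICAL, mirror_point(ih_c), mirrored(ih_ax))
    m.add_joint("hyoid_urohyal_L", "hyoid_L", "urohyal",
                JointType.SPHERICAL, hu_c, hu_ax)
    m.add_joint("hyoid_urohyal_R", "hyoid_R", "urohyal",
                JointType.SPHERICAL, mirror_point(hu_c), mirrored(hu_ax))
    m.add_joint("posttemporal_L", "neurocranium", "posttemporal_L",
                JointType.REVOLUTE, pt_c, [pt_ax])
    m.add_joint("posttemporal_R", "neurocranium", "posttemporal_R",
                JointType.REVOLUTE, mirror_point(pt_c), mirrored(pt_ax))
    m.add_joint("cleithral_L", "posttemporal_L", "cleithrum_L",
                JointType.REVOLUTE, cl_c, [cl_ax])
    m.add_joint("cleithral_R", "posttemporal_R", "cleithrum_R",
                JointType.REVOLUTE, mirror_point(cl_c), mirrored(cl_ax))
    m.add_joint("girdle_midline", "cleithrum_L", "cleithrum_R",
                JointType.UNIVERSAL, gi_c, gi_ax)

    m.add_strut("iom_L", "operculum_L", iom_a, "mandible_L", iom_b)
    m.add_strut("iom_R", "operculum_R", mirror_point(iom_a),
                "mandible_R", mirror_point(iom_b))
    m.add_strut("sternohyoideus", "urohyal", sh_a, "cleithrum_L", sh_b)
    m.finalize()

    par = _parameterization(m)

    if validate:
        _validate_fixture(m, par)

    fps = {}
    for body, pts in g.fit_points.items():
        pts = np.asarray(pts, dtype=float) * g.scale
        fps[body] = FitPointSet(body, pts)
        if body.endswith("_L"):
            rbody = body[:-2] + "_R"
            fps[rbody] = FitPointSet(rbody, np.array(
                [mirror_point(p) for p in pts]))
    return m, par, fps


def _parameterization(m: Mechanism) -> DoFParameterization:
    M = np.zeros((19, m.nq))
    offset = np.zeros(19)
    li = {lab: i for i, lab in enumerate(_LABELS)}

    def coord(joint, k=0):
        return m.coord_slices[joint].start + k

    # strut lengths (offset = rest length so the value is the length itself)
    for lab, strut in (("A", "iom_L"), ("L", "iom_R"),
                       ("B", "sternohyoideus")):
        rec = next(s for s in m.struts if s.name == strut)
        M[li[lab], coord(rec.joint_p)] = 1.0
        offset[li[lab]] = rec.rest_length
    # opercular rotations
    M[li["G"], coord("opercular_L", 0)] = 1.0
    M[li["H"], coord("opercular_L", 1)] = 1.0
    M[li["M"], coord("opercular_R", 0)] = 1.0
    M[li["N"], coord("opercular_R", 1)] = 1.0
    # symmetric / asymmetric pairs
    for sym, asym, jl, jr, k in (
            ("I", "C", "jaw_L", "jaw_R", 0),
            ("J", "F", "susp_cranial_L", "susp_cranial_R", 0),
            ("K", "D", "interhyal_L", "interhyal_R", 0)):
        M[li[sym], coord(jl, k)] = 0.5
        M[li[sym], coord(jr, k)] = 0.5
        M[li[asym], coord(jl, k)] = 0.5
        M[li[asym], coord(jr, k)] = -0.5
    # urohyal yaw: antisymmetric hyoid sweep (the symmetric sweep is
    # urohyal protraction, which the sternohyoideus length B governs)
    M[li["E"], coord("interhyal_L", 1)] = 0.5
    M[li["E"], coord("interhyal_R", 1)] = -0.5
    # long-axis spins
    M[li["O"], coord("interhyal_L", 2)] = 1.0
    M[li["P"], coord("interhyal_R", 2)] = 1.0
    for lab, strut in (("Q", "iom_L"), ("R", "iom_R"),
                       ("S", "sternohyoideus")):
        rec = next(s for s in m.struts if s.name == strut)
        M[li[lab], coord(rec.joint_a, 2)] = 1.0

    return DoFParameterization(mechanism=m, labels=list(_LABELS), matrix=M,
                               offset=offset, groups=dict(_GROUPS),
                               descriptions=dict(_DESCRIPTIONS))


def _validate_fixture(m: Mechanism, par: DoFParameterization) -> None:
    census = m.census_counts()
    expected = {"links": 17, "joints": 21, "joint_dof_sum": 49,
                "loops": 5, "mobility": 19}
    if census != expected:
        raise ValueError(f"fixture census {census} violates required "
                         f"totals {expected}; refusing to build")
    st = m.evaluate(m.zero_q())
    r, J = m.closure_residual(st)
    if np.max(np.abs(r)) > 1e-9:
        raise ValueError("reference conformation does not close all loops")
    nm = numeric_mobility(m)
    if nm != census["mobility"]:
        raise ValueError(f"numeric mobility {nm} != formula mobility "
                         f"{census['mobility']}: special configuration")
    full = np.vstack([J, par.matrix])
    rank = np.linalg.matrix_rank(full, tol=1e-8 * np.linalg.norm(full))
    if rank != m.nq:
        raise ValueError("parameter pins are not independent of the loop "
                         "constraints (singular input map)")


def scaled_geometry(scale_factor: float, jitter_mm: float = 0.0,
                    seed: int | None = None) -> CatfishGeometry:
    """Geometry for an individual of a different size (isotropic scaling)."""
    if scale_factor <= 0:
        raise ValueError("scale factor must be > 0")
    return replace(CatfishGeometry(), scale=scale_factor,
                   head_length=76.0 * scale_factor,
                   jitter_mm=jitter_mm, seed=seed)
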