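"""Fit mechanism input parameters to observed motion and rank degrees of
freedom by sequential freezing.

The central object is the *freeze curve*: starting from a reduced model in
which unmeasurable DoFs are held at fixed values, the remaining DoFs are
frozen one at a time — always the one whose freezing raises the fit error
least — refitting the mechanism to a sample of maximally disparate motion
frames at every step, down to the zero-DoF (akinesis) model.  Errors are
pointwise distances between model-animated and observation-animated fit
points, reported in mm and as a percentage of head length, and judged
against three benchmarks: tracking precision, inter-individual Procrustes
variation, and a percent scale spanning the best and worst models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import FitPointSet, Pose
from .mechanism import (DoFParameterization, Mechanism,
                        forward_kinematics)

__all__ = [
    "FrameFit",
    "FreezeStep",
    "FreezeCurve",
    "Benchmarks",
    "fit_mechanism_frame",
    "sequential_freeze",
    "percent_scale",
    "sufficient_dofs",
    "scale_by_head_length",
    "targets_from_poses",
]


def targets_from_poses(poses: dict[str, Pose],
                       fit_points: dict[str, FitPointSet],
                       bodies: list[str] | None = None,
                       ) -> dict[str, np.ndarray]:
    """Animate each body's fit points by its observed pose -> target points."""
    bodies = list(fit_points) if bodies is None else list(bodies)
    return {b: poses[b].apply(fit_points[b].points)
            for b in bodies if b in poses}


@dataclass
class FrameFit:
    """Result of fitting the free parameters to one motion frame."""

    params: dict[str, float]
    q: np.ndarray
    errors: dict[str, np.ndarray]   # per body: (3,) point distances, mm
    rms: float
    converged: bool
    closure_violation: float = 0.0  # worst loop residual at the solution

    @property
    def pointwise(self) -> np.ndarray:
        return np.concatenate([self.errors[b] for b in sorted(self.errors)])


def fit_mechanism_frame(mech: Mechanism, par: DoFParameterization,
                        targets: dict[str, np.ndarray],
                        fit_points: dict[str, FitPointSet],
                        free: list[str],
                        frozen_values: dict[str, float] | None = None,
                        q_init: np.ndarray | None = None,
                        weights: tuple[float, ...] = (1e3, 1e5),
                        max_nfev: int = 400, xtol: float = 1e-14) -> FrameFit:
    """Fit the free input parameters of one frame to target fit points.

    Minimizes the RMS distance between model-animated and target fit points.
    All joint coordinates are optimized together by Levenberg-Marquardt with
    the loop-closure constraints and the frozen-parameter pins enforced as
    stiff quadratic penalties, annealed through the ``weights`` schedule
    (each stage warm-starts the next).  The graded penalty matters because a
    heavily restricted model can sit exactly at its feasibility boundary —
    frozen soft-tissue lengths straining against the pinned skeleton — where
    a hard constrained solve stalls; the final stage leaves closure
    violations around 1e-6 mm, far below any reported error.

    With ``free == []`` (akinesis at the frozen values) no optimization is
    possible and the errors are simply the distances of the targets from the
    frozen conformation.
    """
    frozen_values = dict(frozen_values or {})
    frozen = [lab for lab in par.labels if lab not in free]
    for lab in frozen:
        frozen_values.setdefault(lab, par.reference_values()[lab])
    bodies = sorted(targets)
    tgt = np.concatenate([np.asarray(targets[b], float).reshape(-1, 3)
                          for b in bodies])
    pts = {b: fit_points[b].points for b in bodies}
    npts = tgt.shape[0]
    q0 = mech.zero_q() if q_init is None else np.asarray(q_init, float).copy()
    nq = mech.nq
    mb = np.stack([mech._moves[:, mech._lidx[b]] for b in bodies]
                  ).astype(float)                       # (nbodies, nq)
    mb_pts = np.repeat(mb, [pts[b].shape[0] for b in bodies], axis=0)
    converged = True

    if free:
        Mfroz, rhs_froz = par.pin_system(frozen_values, frozen)
        cache: dict = {}

        def make_fun(w):
            def fun(q):
                st = mech.evaluate(q)
                r, Jloop = mech.closure_residual(st)
                model = np.concatenate([st.poses[b].apply(pts[b])
                                        for b in bodies])
                # point Jacobian: dy/dq_i = m_i(body) (w_i x (y - p_i) + v_i)
                cols = (np.cross(st.omega[None, :, :],
                                 model[:, None, :] - st.anchor[None, :, :])
                        + st.tdir[None, :, :])          # (npts, nq, 3)
                Jp = (mb_pts[:, :, None] * cols).transpose(0, 2, 1) \
                    .reshape(npts * 3, nq)
                cache["J"] = np.vstack([w * Jloop, w * Mfroz, Jp])
                return np.concatenate([w * r, w * (Mfroz @ q - rhs_froz),
                                       (model - tgt).ravel()])
            return fun

        q = q0
        for w in weights:
            sol = least_squares(make_fun(w), q, jac=lambda x: cache["J"],
                                method="lm", xtol=xtol, ftol=xtol,
                                gtol=1e-14, max_nfev=max_nfev)
            q = sol.x
        converged = bool(sol.status > 0)
    else:
        conf = forward_kinematics(mech, par, frozen_values, init=q0)
        q = conf.q
    st = mech.evaluate(q)
    rclose, _ = mech.closure_residual(st, with_jacobian=False)
    errors = {}
    for b in bodies:
        model = st.poses[b].apply(pts[b])
        errors[b] = np.linalg.norm(
            model - np.asarray(targets[b], float).reshape(-1, 3), axis=1)
    allerr = np.concatenate(list(errors.values()))
    params = par.param_dict(q)
    params.update(frozen_values)
    return FrameFit(params=params, q=q, errors=errors,
                    rms=float(np.sqrt(np.mean(allerr ** 2))),
                    converged=converged,
                    closure_violation=float(np.max(np.abs(rclose)))
                    if len(rclose) else 0.0)


@dataclass
class FreezeStep:
    n_free: int
    frozen_label: str | None          # label newly frozen to reach this step
    free_labels: tuple[str, ...]
    errors_mm: np.ndarray             # pointwise, 3 x bodies x frames
    errors_pcthl: np.ndarray
    median_mm: float
    mean_mm: float


@dataclass
class FreezeCurve:
    """Fit-error distributions indexed by the number of free DoFs."""

    steps: list[FreezeStep]
    freeze_order: list[str]
    head_length: float
    n_frames: int
    n_bodies: int

    def medians(self) -> np.ndarray:
        return np.array([s.median_mm for s in self.steps])

    def means(self) -> np.ndarray:
        return np.array([s.mean_mm for s in self.steps])

    def n_free(self) -> np.ndarray:
        return np.array([s.n_free for s in self.steps])

    def step_for(self, n_free: int) -> FreezeStep:
        for s in self.steps:
            if s.n_free == n_free:
                return s
        raise KeyError(n_free)

    def to_frame(self):
        import pandas as pd
        rows = []
        pm = percent_scale(self, stat="median") if len(self.steps) > 1 \
            else np.full(len(self.steps), np.nan)
        for s, p in zip(self.steps, pm):
            rows.append({"free_dofs": s.n_free,
                         "frozen_label": s.frozen_label or "",
                         "median_error_mm": s.median_mm,
                         "mean_error_mm": s.mean_mm,
                         "median_error_pcthl": float(np.median(s.errors_pcthl)),
                         "percent_scale_median": float(p)})
        return pd.DataFrame(rows)


def sequential_freeze(mech: Mechanism, par: DoFParameterization,
                      frame_targets: list[dict[str, np.ndarray]],
                      fit_points: dict[str, FitPointSet],
                      start_free: list[str],
                      freeze_values: dict[str, float],
                      head_length: float,
                      max_steps: int | None = None,
                      statistic: str = "median",
                      fit_max_nfev: int = 150,
                      fit_xtol: float = 1e-10,
                      q_inits: list[np.ndarray] | None = None,
                      progress: bool = False) -> FreezeCurve:
    """Greedy sequential DoF freezing with full refits at every step.

    ``frame_targets`` holds the sampled (most disparate) frames' fit-point
    targets per scored body.  ``start_free`` is the initial free set (the
    a-priori-unmeasurable DoFs are already absent from it) and
    ``freeze_values`` the values at which DoFs are held when frozen — by
    convention their means over the full fitted trajectory.

    At each step, every remaining free DoF is trial-frozen, all frames are
    refit, and the DoF whose freezing increases the pooled error statistic
    (median by default, matching the box-plot presentation of freeze
    curves; mean weights localized single-element effects more faithfully)
    the least is frozen permanently; ties resolve in label order, making
    runs reproducible.  Terminates at the zero-DoF (akinesis) model unless
    ``max_steps`` stops it earlier.

    ``q_inits`` optionally warm-starts the first full-model fit per frame
    (typically from a prior full-trajectory fit); candidate fits always
    warm-start from the accepted parent step.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    stat_fn = np.median if statistic == "median" else np.mean
    order_key = {lab: i for i, lab in enumerate(par.labels)}
    free = sorted(start_free, key=order_key.__getitem__)
    frozen_vals = {lab: freeze_values.get(lab, par.reference_values()[lab])
                   for lab in par.labels if lab not in free}

    def fit_all(free_now, fv, warm):
        errs, qs = [], []
        for i, tg in enumerate(frame_targets):
            fr = fit_mechanism_frame(mech, par, tg, fit_points, free_now, fv,
                                     q_init=warm[i], max_nfev=fit_max_nfev,
                                     xtol=fit_xtol)
            errs.append(fr.pointwise)
            qs.append(fr.q)
        return np.concatenate(errs), qs

    warm = list(q_inits) if q_inits is not None \
        else [None] * len(frame_targets)
    errs, warm = fit_all(free, frozen_vals, warm)
    n_bodies = len(frame_targets[0])
    steps = [FreezeStep(len(free), None, tuple(free), errs,
                        scale_by_head_length(errs, head_length),
                        float(np.median(errs)), float(np.mean(errs)))]
    freeze_order: list[str] = []
    while free and (max_steps is None or len(freeze_order) < max_steps):
        best = None
        for lab in free:     # label order == tie-break order
            trial_free = [x for x in free if x != lab]
            fv = dict(frozen_vals)
            fv[lab] = freeze_values.get(lab, par.reference_values()[lab])
            e, qs = fit_all(trial_free, fv, warm)
            cost = float(stat_fn(e))
            if best is None or cost < best[0] - 1e-15:
                best = (cost, lab, e, qs)
        cost, lab, e, qs = best
        free = [x for x in free if x != lab]
        frozen_vals[lab] = freeze_values.get(lab, par.reference_values()[lab])
        warm = qs
        freeze_order.append(lab)
        steps.append(FreezeStep(len(free), lab, tuple(free), e,
                                scale_by_head_length(e, head_length),
                                float(np.median(e)), float(np.mean(e))))
        if progress:
            print(f"froze {lab}: {len(free)} free, "
                  f"{statistic} error {cost:.4f} mm")
    return FreezeCurve(steps=steps, freeze_order=freeze_order,
                       head_length=head_length, n_frames=len(frame_targets),
                       n_bodies=n_bodies)


@dataclass
class Benchmarks:
    """The three yardsticks for judging model fit error.

    ``precision_mm``: tracking precision (RMS marker-configuration deviation
    over random frames).  ``interindividual_mm`` (and as % head length): RMS
    landmark deviation of each individual from a Procrustes consensus.  The
    percent-scale anchors are the median errors of the highest- and
    lowest-parameter models of a freeze curve.
    """

    precision_mm: float
    interindividual_mm: float
    interindividual_pcthl: float
    best_median_mm: float = float("nan")
    worst_median_mm: float = float("nan")
    per_body_precision: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.best_median_mm) and \
                np.isfinite(self.worst_median_mm):
            if self.best_median_mm > self.worst_median_mm + 1e-12:
                raise ValueError("anchor ordering violated: best (highest-"
                                 "parameter) median exceeds worst")

    @staticmethod
    def from_curve(curve: FreezeCurve, precision_mm: float,
                   interindividual_mm: float) -> "Benchmarks":
        return Benchmarks(
            precision_mm=precision_mm,
            interindividual_mm=interindividual_mm,
            interindividual_pcthl=scale_by_head_length(
                interindividual_mm, curve.head_length),
            best_median_mm=curve.steps[0].median_mm,
            worst_median_mm=curve.steps[-1].median_mm)


def percent_scale(curve: FreezeCurve, stat: str = "median") -> np.ndarray:
    """Each step's error as a percent of the best-to-worst error span.

    0% is the highest-parameter (best) model, 100% the lowest-parameter
    (akinesis) model: ``100 * (e - e_best) / (e_worst - e_best)``.
    """
    if len(curve.steps) < 2:
        raise ValueError("need at least two steps for a percent scale")
    vals = curve.medians() if stat == "median" else curve.means()
    best, worst = vals[0], vals[-1]
    if abs(worst - best) < 1e-15:
        raise ValueError("percent scale undefined: best and worst errors "
                         "coincide")
    return 100.0 * (vals - best) / (worst - best)


def sufficient_dofs(curve: FreezeCurve, benchmarks: Benchmarks | None = None,
                    criterion: str = "benchmark",
                    percent_threshold: float = 9.0,
                    stat: str = "mean",
                    apriori_frozen: tuple[str, ...] = (),
                    ) -> tuple[int, dict]:
    """Smallest free-DoF count whose error satisfies the chosen criterion.

    ``criterion='benchmark'``: the step's error statistic must fall below the
    inter-individual variation benchmark.  ``criterion='percent'``: the
    step's percent-scale value must not exceed ``percent_threshold``.

    The rationale record also reports the *bilateral-equivalent* count: when
    the chosen model keeps unilateral opercular DoFs (G, H) free while their
    contralateral twins (M, N) were frozen a priori for lack of measurement,
    a symmetric animal would use correspondingly more DoFs (e.g. a 5-DoF
    unilateral model is equivalent to a 7-DoF bilateral one).
    """
    stats = curve.means() if stat == "mean" else curve.medians()
    if criterion == "percent":
        pct = percent_scale(curve, stat=stat)
        ok = pct <= percent_threshold + 1e-12
        threshold_desc = f"percent scale <= {percent_threshold}"
    elif criterion == "benchmark":
        if benchmarks is None:
            raise ValueError("benchmark criterion needs Benchmarks")
        ok = stats < benchmarks.interindividual_mm
        threshold_desc = (f"{stat} error < inter-individual benchmark "
                          f"{benchmarks.interindividual_mm:.4g} mm")
    else:
        raise ValueError(criterion)
    satisfied = np.flatnonzero(ok)
    if len(satisfied) == 0:
        step = curve.steps[0]
        flag = False
    else:
        # steps are ordered by decreasing free DoFs; the last satisfying
        # step has the fewest free DoFs
        step = curve.steps[int(satisfied[-1])]
        flag = True
    k = step.n_free
    twins = 0
    if {"M", "N"} <= set(apriori_frozen):
        twins = len({"G", "H"} & set(step.free_labels))
    rationale = {
        "criterion": threshold_desc,
        "satisfied": flag,
        "free_labels": list(step.free_labels),
        "stat": stat,
        "value_mm": float(stats[curve.steps.index(step)]),
        "bilateral_equivalent": k + twins,
    }
    return k, rationale


def scale_by_head_length(errors, head_length: float):
    """Express errors (mm) as a percentage of head length."""
    if head_length <= 0:
        raise ValueError("head length must be > 0")
    out = np.asarray(errors, dtype=float) * 100.0 / head_length
    return float(out) if out.ndim == 0 else out
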