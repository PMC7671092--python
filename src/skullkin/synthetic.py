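"""Ground-truthed synthetic recordings with the statistical structure the
analysis assumes.

The generator emulates an X-ray motion-capture study of suction feeding in a
catfish-like skull: wave-patterned trajectories on the five primary DoFs
drive the five-loop mechanism (soft-tissue lengths follow the skeleton),
markers rigidly attached to a unilateral subset of bodies are observed
through isotropic Gaussian noise with occasional missing frames, and a prey
marker moves with a class-matched rostrocaudal velocity profile.  Every
random choice flows from one seed through named substreams, so a recording
is fully reproducible.

Default conditions mirror the study design this package is built around:
300 Hz frames, 0.08 mm marker noise (the tracking precision of good
biplanar fluoroscopy), ~0.5 s feeding events, 20 ms inter-stage peak lags
and 80 ms bump widths.  Per-DoF amplitudes are order-of-magnitude choices
(tens of degrees for mandibular/hyoid motion, less for opercular rotations);
no published numeric trace values stand behind them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MarkerTrajectory, Pose
from .fixture import MARKED_BODIES, CatfishGeometry, scaled_geometry
from .mechanism import (ClosureError, Conformation, DoFParameterization,
                        Mechanism, forward_kinematics)
from .waves import PreyTrack

__all__ = [
    "WaveSpec",
    "WaveTrain",
    "SyntheticRecording",
    "default_wave_spec",
    "generate_wave_trajectories",
    "simulate_recording",
    "make_individual",
]

_LAG = 0.020     # s between successive peaks along the wave
_WIDTH = 0.080   # s Gaussian bump width (sigma)


@dataclass
class WaveSpec:
    """Template for one class of feeding event.

    ``amplitudes`` (rad) and ``peak_offsets`` (s, relative to the event
    center) are keyed by parameter label (I, J, K, G, H).  ``rise_sigma``
    optionally widens the rising flank of a label's bump (used for the
    slow-open class).  The prey pulse is described by amplitude (mm/s,
    positive = caudal), offset from the class alignment peak (s) and width
    (s).
    """

    klass: str
    amplitudes: dict[str, float]
    peak_offsets: dict[str, float]
    width_s: float = _WIDTH
    rise_sigma: dict[str, float] = field(default_factory=dict)
    prey_amp: float = 0.0
    prey_offset_s: float = 0.0
    prey_width_s: float = 0.05
    jitter_time_s: float = 0.004
    jitter_amp_frac: float = 0.08

    def __post_init__(self):
        labs = set(self.amplitudes)
        if labs != set(self.peak_offsets):
            raise ValueError("amplitudes and peak_offsets must share labels")
        off = self.peak_offsets
        if self.klass == "rostrocaudal":
            seq = [off[l] for l in ("I", "J", "K", "G", "H") if l in off]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError("rostrocaudal spec needs rostral-to-caudal "
                                 "increasing peak times")
        elif self.klass == "caudorostral":
            seq = [off[l] for l in ("I", "J", "K", "G", "H") if l in off]
            if any(b >= a for a, b in zip(seq, seq[1:])):
                raise ValueError("caudorostral spec needs decreasing "
                                 "peak times")
        elif self.klass == "compressive":
            if self.amplitudes.get("K", 0.0) >= 0:
                raise ValueError("compressive spec needs hyoid elevation "
                                 "(negative K amplitude)")
            if off.get("K", 0.0) >= off.get("H", 0.0):
                raise ValueError("compressive spec needs hyoid elevation "
                                 "preceding flaring")

    @property
    def alignment_label(self) -> str:
        return "I" if self.klass in ("rostrocaudal", "slow_open") else "H"


def default_wave_spec(klass: str) -> WaveSpec:
    """The built-in template for each of the four generated classes.

    Prey-velocity templates encode the qualitative contrasts of the study
    system: a sharp caudal pulse at peak gape for the rostrocaudal wave, a
    slower, broader rostral pulse ~100 ms after peak flaring for the
    caudorostral wave, and a caudal pulse an order of magnitude weaker than
    the rostrocaudal one for the compressive wave.
    """
    if klass == "rostrocaudal":
        return WaveSpec(
            klass,
            amplitudes={"I": 0.35, "J": 0.15, "K": 0.25, "G": 0.12,
                        "H": 0.10},
            peak_offsets={"I": 0.0, "J": _LAG, "K": 2 * _LAG, "G": 3 * _LAG,
                          "H": 4 * _LAG},
            prey_amp=300.0, prey_offset_s=0.005, prey_width_s=0.04)
    if klass == "caudorostral":
        return WaveSpec(
            klass,
            amplitudes={"I": 0.10, "J": 0.12, "K": 0.16, "G": 0.15,
                        "H": 0.22},
            peak_offsets={"I": 4 * _LAG, "J": 3 * _LAG, "K": 2 * _LAG,
                          "G": _LAG, "H": 0.0},
            prey_amp=-80.0, prey_offset_s=0.100, prey_width_s=0.08)
    if klass == "compressive":
        return WaveSpec(
            klass,
            amplitudes={"I": 0.012, "J": 0.04, "K": -0.18, "G": 0.08,
                        "H": 0.15},
            peak_offsets={"I": 0.0, "J": 0.02, "K": -0.05, "G": 0.03,
                          "H": 0.0},
            prey_amp=25.0, prey_offset_s=0.060, prey_width_s=0.08)
    if klass == "slow_open":
        return WaveSpec(
            klass,
            amplitudes={"I": 0.25, "J": 0.03, "K": 0.04, "G": 0.02,
                        "H": 0.02},
            peak_offsets={"I": 0.0, "J": 0.01, "K": 0.02, "G": 0.03,
                          "H": 0.04},
            rise_sigma={"I": 0.35},
            prey_amp=0.0)
    raise ValueError(f"no template for class {klass!r}")


@dataclass
class WaveTrain:
    """Parameter trajectories plus event ground truth."""

    params: pd.DataFrame            # columns = labels, one row per frame
    frame_rate: float
    event_times: list[float]        # alignment-peak time per event (s)
    event_classes: list[str]
    prey_velocity: np.ndarray       # mm/s, rostrocaudal

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.params)) / self.frame_rate


def _bump(t, t0, amp, sigma, rise_sigma=None):
    s = np.where(t < t0, rise_sigma if rise_sigma else sigma, sigma)
    return amp * np.exp(-0.5 * ((t - t0) / s) ** 2)


def generate_wave_trajectories(spec: WaveSpec | list[WaveSpec],
                               n_events: int, fs: float = 300.0,
                               seed: int | None = 0,
                               spacing_s: float = 1.2,
                               lead_s: float = 0.5) -> WaveTrain:
    """Smooth bump-train trajectories for the five primary DoFs.

    Events are spaced ``spacing_s`` apart (must exceed one event window plus
    the largest peak offset); per-event timing and amplitude jitter come
    from the seed.  Passing a list of specs cycles through them, labelling
    each event with its generating class.  The same seed always reproduces
    the same train.
    """
    if fs <= 0:
        raise ValueError("frame rate must be > 0")
    specs = [spec] if isinstance(spec, WaveSpec) else list(spec)
    span = max(max(abs(v) for v in s.peak_offsets.values()) for s in specs)
    if spacing_s < 2 * span + 0.3:
        raise ValueError("events would overlap: increase spacing_s")
    rng = np.random.default_rng(seed)
    duration = lead_s * 2 + spacing_s * max(n_events - 1, 0) + 0.5
    t = np.arange(int(round(duration * fs))) / fs
    traj = {lab: np.zeros_like(t) for lab in ("I", "J", "K", "G", "H")}
    prey = np.zeros_like(t)
    event_times, event_classes = [], []
    for e in range(n_events):
        s = specs[e % len(specs)]
        t0 = lead_s + e * spacing_s + rng.normal(0.0, s.jitter_time_s)
        event_times.append(float(t0))
        event_classes.append(s.klass)
        for lab, amp in s.amplitudes.items():
            a = amp * (1.0 + rng.normal(0.0, s.jitter_amp_frac))
            dt0 = rng.normal(0.0, s.jitter_time_s)
            traj[lab] += _bump(t, t0 + s.peak_offsets[lab] + dt0, a,
                               s.width_s, s.rise_sigma.get(lab))
        if s.prey_amp != 0.0:
            pa = s.prey_amp * (1.0 + rng.normal(0.0, s.jitter_amp_frac))
            prey += _bump(t, t0 + s.prey_offset_s, pa, s.prey_width_s)
    params = pd.DataFrame(traj)
    return WaveTrain(params=params, frame_rate=fs, event_times=event_times,
                     event_classes=event_classes, prey_velocity=prey)


@dataclass
class SyntheticRecording:
    """A complete simulated trial with its ground truth."""

    mechanism: Mechanism
    parameterization: DoFParameterization
    params_true: pd.DataFrame        # all 19 labels per frame (post-closure)
    poses: dict[str, list[Pose]]
    markers: list[MarkerTrajectory]
    frame_rate: float
    head_length: float
    marked_bodies: tuple[str, ...]
    noise_mm: float
    prey: PreyTrack | None
    seed: int | None
    wave: WaveTrain | None = None

    def markers_by_body(self) -> dict[str, list[MarkerTrajectory]]:
        out: dict[str, list[MarkerTrajectory]] = {}
        for tr in self.markers:
            out.setdefault(tr.body, []).append(tr)
        return out


def _marker_offsets(fit_points: np.ndarray, n_markers: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Marker sites on a body: the fit points plus extra scattered points."""
    pts = [fit_points]
    need = n_markers - fit_points.shape[0]
    if need > 0:
        c = fit_points.mean(axis=0)
        spread = max(float(np.ptp(fit_points)), 4.0)
        extra = c + rng.normal(0.0, 0.25 * spread, size=(need, 3))
        pts.append(extra)
    return np.vstack(pts)[:n_markers]


def simulate_recording(mech: Mechanism, par: DoFParameterization,
                       trajectories: pd.DataFrame | WaveTrain,
                       fit_points: dict,
                       markers_per_body: int = 4,
                       noise_mm: float = 0.08,
                       missing_rate: float = 0.0,
                       marked_bodies: tuple[str, ...] | None = MARKED_BODIES,
                       frame_rate: float = 300.0,
                       head_length: float = 76.0,
                       seed: int | None = 0) -> SyntheticRecording:
    """Drive the mechanism through parameter trajectories and observe markers.

    ``trajectories`` supplies per-frame values for any subset of labels
    (typically the five primary DoFs); unlisted rotations stay at their
    reference values and the soft-tissue lengths (A, B, L) follow the
    skeleton through loop closure.  Markers rigidly attached to
    ``marked_bodies`` are perturbed with iid Gaussian noise of ``noise_mm``
    and masked missing at ``missing_rate``; a kinematic failure at any frame
    aborts with the frame index.

    The returned ground truth holds the full post-closure parameter vector
    per frame, so even the settled lengths are known exactly.
    """
    wave = None
    if isinstance(trajectories, WaveTrain):
        wave = trajectories
        frame_rate = trajectories.frame_rate
        trajectories = trajectories.params
    driven = [c for c in trajectories.columns if c in par.labels]
    free_len = tuple(lab for lab in par.groups.get("lengths", ())
                     if lab not in driven)
    if marked_bodies is None:
        marked_bodies = tuple(sorted(fit_points))
    if markers_per_body < 3:
        raise ValueError("marked bodies need at least 3 markers")
    ref = par.reference_values()
    n_frames = len(trajectories)
    rng_markers = np.random.default_rng(None if seed is None else seed)
    rng_noise = np.random.default_rng(None if seed is None else seed + 1)
    rng_miss = np.random.default_rng(None if seed is None else seed + 2)

    poses: dict[str, list[Pose]] = {b: [] for b in mech.links}
    rows = []
    conf: Conformation | None = None
    for f in range(n_frames):
        vals = dict(ref)
        for lab in driven:
            vals[lab] = float(trajectories.iloc[f][lab])
        try:
            conf = forward_kinematics(mech, par, vals, init=conf,
                                      free_labels=free_len)
        except ClosureError as e:
            raise ClosureError(
                f"kinematic failure at frame {f}: {e}", loop=e.loop) from e
        rows.append(conf.params)
        for b in mech.links:
            poses[b].append(conf.poses[b])
    params_true = pd.DataFrame(rows)

    markers: list[MarkerTrajectory] = []
    for b in marked_bodies:
        offs = _marker_offsets(fit_points[b].points, markers_per_body,
                               rng_markers)
        for k in range(offs.shape[0]):
            world = np.stack([poses[b][f].apply(offs[k])
                              for f in range(n_frames)])
            if noise_mm > 0:
                world = world + rng_noise.normal(0.0, noise_mm,
                                                 size=world.shape)
            missing = rng_miss.random(n_frames) < missing_rate
            world[missing] = np.nan
            markers.append(MarkerTrajectory(f"{b}_m{k}", b, world,
                                            frame_rate, missing))

    prey = None
    if wave is not None and np.any(wave.prey_velocity != 0.0):
        x = 40.0 + np.cumsum(wave.prey_velocity) / frame_rate
        pos = np.column_stack([x, np.zeros_like(x), np.full_like(x, -8.0)])
        prey = PreyTrack(pos, frame_rate)
    return SyntheticRecording(
        mechanism=mech, parameterization=par, params_true=params_true,
        poses=poses, markers=markers, frame_rate=frame_rate,
        head_length=head_length, marked_bodies=tuple(marked_bodies),
        noise_mm=noise_mm, prey=prey, seed=seed, wave=wave)


def make_individual(scale_factor: float = 1.0, seed: int | None = None,
                    jitter_mm: float = 0.0) -> tuple[CatfishGeometry, float]:
    """Geometry config for one individual: isotropic scale + optional jitter.

    Returns ``(geometry, head_length_mm)``; head length scales linearly with
    the factor.  With jitter, joint centers and strut anchors are perturbed
    by iid Gaussian offsets of ``jitter_mm``, emulating inter-individual
    shape variation.
    """
    geo = scaled_geometry(scale_factor, jitter_mm=jitter_mm, seed=seed)
    return geo, geo.head_length
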