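"""Cranial expansion-wave analysis: event detection, classification,
alignment and prey-velocity association.

Suction-feeding fish drive food with travelling waves of cranial expansion.
Working from the five primary DoF traces — mandibular depression (gape),
suspensorial abduction, hyoid depression, opercular abduction and opercular
flaring out — this module finds ~0.5 s event windows around gape and/or
flaring peaks, classifies each window as a rostrocaudal wave (front-to-back
expansion, sucking food caudally), a caudorostral wave (back-to-front,
pushing food rostrally), a compressive wave (hyoid elevation then opercular
flaring, slow caudal food motion), a slow-open wave, or unknown, and
aggregates aligned traces with the food's rostrocaudal velocity.

Classification here is an explicit, threshold-based surrogate for expert
labeling; every threshold lives in :class:`ClassifierThresholds`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DOF_NAMES",
    "DOF_LABEL_MAP",
    "WAVE_CLASSES",
    "DoFTraces",
    "MotionEvent",
    "PreyTrack",
    "ClassifierThresholds",
    "detect_events",
    "classify_event",
    "align_and_aggregate",
    "prey_velocity_rc",
]

#: The five primary DoF trace names, rostral to caudal.
DOF_NAMES = ("mandibular_depression", "suspensorial_abduction",
             "hyoid_depression", "opercular_abduction",
             "opercular_flaring_out")

#: Mechanism parameter label carrying each trace.
DOF_LABEL_MAP = {"mandibular_depression": "I",
                 "suspensorial_abduction": "J",
                 "hyoid_depression": "K",
                 "opercular_abduction": "G",
                 "opercular_flaring_out": "H"}

WAVE_CLASSES = ("rostrocaudal", "caudorostral", "compressive", "slow_open",
                "unknown")

#: Alignment reference per class: gape peak or opercular-flaring peak.
ALIGNMENT_REFERENCE = {"rostrocaudal": "gape", "slow_open": "gape",
                       "caudorostral": "flaring", "compressive": "flaring"}


@dataclass
class DoFTraces:
    """The five primary DoF time series (rad) on a common time base."""

    mandibular_depression: np.ndarray
    suspensorial_abduction: np.ndarray
    hyoid_depression: np.ndarray
    opercular_abduction: np.ndarray
    opercular_flaring_out: np.ndarray
    frame_rate: float

    def __post_init__(self):
        lengths = set()
        for name in DOF_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            setattr(self, name, arr)
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValueError("all five traces must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.mandibular_depression.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in DOF_NAMES}

    @staticmethod
    def from_params(params: pd.DataFrame, frame_rate: float) -> "DoFTraces":
        """Build from a parameter-trajectory table with columns I,J,K,G,H."""
        return DoFTraces(
            frame_rate=frame_rate,
            **{name: params[lab].to_numpy()
               for name, lab in DOF_LABEL_MAP.items()})


@dataclass
class MotionEvent:
    """A windowed, time-aligned feeding event.

    ``t_ref`` is the alignment reference time: the gape peak for
    rostrocaudal and slow-open waves, the opercular-flaring peak for
    caudorostral and compressive waves.  ``segments`` holds the five DoF
    traces over the window; peak times are absolute (s).
    """

    start: float
    end: float
    t_ref: float
    ref_kind: str                     # 'gape' or 'flaring'
    times: np.ndarray
    segments: dict[str, np.ndarray]
    peak_times: dict[str, float] = field(default_factory=dict)
    peak_amps: dict[str, float] = field(default_factory=dict)
    klass: str = "unknown"
    event_id: int = -1

    def __post_init__(self):
        if not (self.start <= self.t_ref <= self.end):
            raise ValueError("alignment reference must lie inside the window")


@dataclass
class PreyTrack:
    """Prey-marker positions in the neurocranium anatomical frame (mm).

    The rostrocaudal coordinate is +x (positive velocity = caudally
    directed).  ``exclude`` flags frames that must not contribute velocity
    (prey resting on the tank bottom or already in the esophagus).
    """

    positions: np.ndarray
    frame_rate: float
    exclude: np.ndarray | None = None
    smoothing_cutoff: float = 25.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if self.exclude is None:
            self.exclude = np.zeros(self.positions.shape[0], dtype=bool)
        self.exclude = np.asarray(self.exclude, dtype=bool).reshape(-1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) / self.frame_rate

    def velocity_rc(self) -> np.ndarray:
        """Rostrocaudal velocity (mm/s): low-pass smoothed, central
        differences."""
        x = self.positions[:, 0]
        nyq = self.frame_rate / 2.0
        if 0 < self.smoothing_cutoff < nyq and x.shape[0] > 15:
            b, a = signal.butter(2, self.smoothing_cutoff / nyq)
            x = signal.filtfilt(b, a, x)
        return np.gradient(x, 1.0 / self.frame_rate)


@dataclass
class ClassifierThresholds:
    """All quantitative rules of the wave classifier, in one place.

    ``amplitude_dominance``: gape below this fraction of the largest other
    amplitude counts as "minimal gape".  ``peak_order_margin_s``: slack when
    comparing peak times.  ``slow_rise_s``: a gape rise time (10%-of-peak to
    peak) beyond this is a slow-open wave.  ``min_amplitude``: amplitudes
    below this (rad) are treated as absent.
    """

    amplitude_dominance: float = 0.1
    peak_order_margin_s: float = 0.005
    slow_rise_s: float = 0.250
    min_amplitude: float = 0.01


def _peak_centroid(times, x, level: float = 0.6):
    """Robust peak time: centroid of the contiguous region around the
    maximum where the trace exceeds ``level`` of the peak value.  Far more
    stable than a raw argmax for broad bumps observed through noise."""
    i = int(np.argmax(x))
    peak = x[i]
    if peak <= 0:
        return float(times[i]), float(peak)
    thr = level * peak
    lo = i
    while lo > 0 and x[lo - 1] >= thr:
        lo -= 1
    hi = i
    while hi < len(x) - 1 and x[hi + 1] >= thr:
        hi += 1
    w = x[lo:hi + 1] - thr
    if w.sum() <= 0:
        return float(times[i]), float(peak)
    return float(np.sum(times[lo:hi + 1] * w) / np.sum(w)), float(peak)


def _window_peaks(times, segments):
    """Per-DoF peak time and signed amplitude within one window.

    For hyoid depression both the maximum (depression) and the minimum
    (elevation) are recorded, since compressive waves start with elevation.
    """
    pt, pa = {}, {}
    for name in DOF_NAMES:
        t, v = _peak_centroid(times, segments[name])
        pt[name] = t
        pa[name] = v
    t, v = _peak_centroid(times, -segments["hyoid_depression"])
    pt["hyoid_elevation"] = t
    pa["hyoid_elevation"] = v   # positive = elevation magnitude
    return pt, pa


def detect_events(traces: DoFTraces, window_s: float = 0.5,
                  prominence: float = 0.05) -> list[MotionEvent]:
    """Find event windows around gape and/or opercular-flaring peaks.

    Peaks of mandibular depression and opercular flaring out exceeding
    ``prominence`` (rad) seed windows of ``window_s`` centered on the peak;
    a gape peak and a flaring peak closer than half a window merge into one
    event (the reference peak is chosen later by the classifier).
    """
    if traces.n_frames == 0:
        raise ValueError("empty traces")
    if traces.n_frames / traces.frame_rate < window_s:
        raise ValueError("traces shorter than one event window")
    t = traces.times
    gape = traces.mandibular_depression
    flare = traces.opercular_flaring_out
    pg, _ = signal.find_peaks(gape, prominence=prominence)
    pf, _ = signal.find_peaks(flare, prominence=prominence)
    cands = sorted([(int(i), "gape") for i in pg]
                   + [(int(i), "flaring") for i in pf])
    merged: list[list] = []
    for idx, kind in cands:
        if merged and t[idx] - t[merged[-1][0]] < window_s / 2.0:
            merged[-1].append(idx)
            merged[-1] = sorted(set(merged[-1][:1] + merged[-1][1:]))
            # keep the dominant peak of the merged cluster as the center
            center = max(merged[-1], key=lambda i: max(gape[i], flare[i]))
            merged[-1] = [center] + [i for i in merged[-1] if i != center]
        else:
            merged.append([idx])
    events = []
    half = window_s / 2.0
    for eid, cluster in enumerate(merged):
        center = cluster[0]
        t0 = t[center]
        sel = (t >= t0 - half) & (t <= t0 + half)
        if sel.sum() < 3:
            continue
        times_w = t[sel]
        segs = {name: traces.as_dict()[name][sel].copy()
                for name in DOF_NAMES}
        pt, pa = _window_peaks(times_w, segs)
        ref_kind = "gape" if gape[center] >= flare[center] else "flaring"
        t_ref = pt["mandibular_depression"] if ref_kind == "gape" \
            else pt["opercular_flaring_out"]
        events.append(MotionEvent(
            start=float(times_w[0]), end=float(times_w[-1]),
            t_ref=float(np.clip(t_ref, times_w[0], times_w[-1])),
            ref_kind=ref_kind, times=times_w, segments=segs,
            peak_times=pt, peak_amps=pa, event_id=eid))
    return events


def _gape_rise_time(times, gape) -> float:
    """Time from the last 10%-of-peak crossing to the gape peak."""
    i = int(np.argmax(gape))
    peak = gape[i]
    if peak <= 0:
        return 0.0
    below = np.flatnonzero(gape[:i + 1] < 0.1 * peak)
    if len(below) == 0:
        # gape already elevated at the window edge: the rise started before
        # the window, i.e. it is at least window-long
        return float("inf")
    return float(times[i] - times[below[-1]])


def classify_event(event: MotionEvent,
                   thresholds: ClassifierThresholds | None = None) -> str:
    """Assign a wave class from relative peak amplitudes and timing.

    Rules (checked in order; ``unknown`` is the fallback):

    * *slow-open*: gape dominates and its rise time exceeds the slowness
      threshold;
    * *compressive*: minimal gape, and hyoid elevation precedes the
      opercular-flaring peak;
    * *rostrocaudal*: substantial gape, mandible peaks first and an
      opercular rotation peaks last (rostral-to-caudal sequence);
    * *caudorostral*: flaring peaks first and the mandible peaks last
      (caudal-to-rostral sequence).

    Classification is invariant to uniform amplitude scaling of all five
    traces and to absolute time shifts.  Sets ``event.klass``, and realigns
    ``event.t_ref`` to the class's reference peak.
    """
    th = thresholds or ClassifierThresholds()
    pt, pa = event.peak_times, event.peak_amps
    m = th.peak_order_margin_s
    amp_scale = max(max(abs(v) for v in pa.values()), 1e-30)

    def amp(name):
        return pa[name] / amp_scale

    gape_amp = amp("mandibular_depression")
    others = [amp("suspensorial_abduction"), amp("hyoid_depression"),
              amp("hyoid_elevation"), amp("opercular_abduction"),
              amp("opercular_flaring_out")]
    biggest_other = max(others)
    t_mand = pt["mandibular_depression"]
    t_susp = pt["suspensorial_abduction"]
    t_hyo = pt["hyoid_depression"]
    t_opab = pt["opercular_abduction"]
    t_flar = pt["opercular_flaring_out"]
    klass = "unknown"
    rise = _gape_rise_time(event.times, event.segments["mandibular_depression"])

    if gape_amp >= biggest_other and rise > th.slow_rise_s:
        klass = "slow_open"
    elif (gape_amp < th.amplitude_dominance * biggest_other
          and amp("hyoid_elevation") > th.amplitude_dominance * biggest_other
          and pt["hyoid_elevation"] < t_flar - m):
        klass = "compressive"
    elif (gape_amp >= th.amplitude_dominance * biggest_other
          and t_mand <= min(t_susp, t_hyo, t_opab, t_flar) + m
          and max(t_opab, t_flar) >= max(t_susp, t_hyo) - m):
        klass = "rostrocaudal"
    elif (t_flar <= min(t_mand, t_susp, t_hyo, t_opab) + m
          and t_mand >= max(t_susp, t_hyo) - m):
        klass = "caudorostral"
    event.klass = klass
    ref_kind = ALIGNMENT_REFERENCE.get(klass,
                                       event.ref_kind)
    event.ref_kind = ref_kind
    t_ref = t_mand if ref_kind == "gape" else t_flar
    event.t_ref = float(np.clip(t_ref, event.start, event.end))
    return klass


def align_and_aggregate(events: list[MotionEvent], klass: str,
                        grid_hz: float = 300.0) -> pd.DataFrame:
    """Mean and standard error of aligned DoF traces for one event class.

    Each event is resampled onto a common time grid relative to its
    alignment reference; columns are ``t_rel_s``, ``mean_<dof>`` and
    ``se_<dof>``.
    """
    sel = [e for e in events if e.klass == klass]
    if not sel:
        raise ValueError(f"no events of class {klass!r}")
    if any(e.klass != klass for e in sel):
        raise ValueError("mixed classes")
    half = min(min(e.t_ref - e.start, e.end - e.t_ref) for e in sel)
    n = max(int(np.floor(half * grid_hz)), 1)
    grid = np.arange(-n, n + 1) / grid_hz
    out = {"t_rel_s": grid}
    for name in DOF_NAMES:
        stack = np.stack([np.interp(grid, e.times - e.t_ref,
                                    e.segments[name]) for e in sel])
        out[f"mean_{name}"] = stack.mean(axis=0)
        out[f"se_{name}"] = (stack.std(axis=0, ddof=1) / np.sqrt(len(sel))
                             if len(sel) > 1 else np.zeros_like(grid))
    return pd.DataFrame(out)


def prey_velocity_rc(prey: PreyTrack, events: list[MotionEvent],
                     klass: str, grid_hz: float = 300.0) -> pd.DataFrame:
    """Class-aggregated rostrocaudal prey-velocity profile.

    Events whose window overlaps excluded prey frames (on the bottom, in the
    esophagus) carry no velocity and are dropped.  Positive velocity is
    caudally directed.
    """
    sel = [e for e in events if e.klass == klass]
    if not sel:
        raise ValueError(f"no events of class {klass!r}")
    vel = prey.velocity_rc()
    t = prey.times
    half = min(min(e.t_ref - e.start, e.end - e.t_ref) for e in sel)
    n = max(int(np.floor(half * grid_hz)), 1)
    grid = np.arange(-n, n + 1) / grid_hz
    profiles = []
    for e in sel:
        win = (t >= e.start) & (t <= e.end)
        if prey.exclude[win].any() or win.sum() < 3:
            continue
        profiles.append(np.interp(grid, t[win] - e.t_ref, vel[win]))
    out = {"t_rel_s": grid}
    if profiles:
        stack = np.stack(profiles)
        out["mean_preyvel"] = stack.mean(axis=0)
        out["se_preyvel"] = (stack.std(axis=0, ddof=1)
                             / np.sqrt(len(profiles))
                             if len(profiles) > 1 else np.zeros_like(grid))
        out["n_events"] = np.full(grid.shape, len(profiles))
    else:
        out["mean_preyvel"] = np.full(grid.shape, np.nan)
        out["se_preyvel"] = np.full(grid.shape, np.nan)
        out["n_events"] = np.zeros(grid.shape)
    return pd.DataFrame(out)
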