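"""Synthetic data with ground truth: tube-test bouts, photometry, OFSI.

No animal data ships with this package, so every downstream stage is
exercised against generated inputs whose ground truth is known exactly:

* Scripted tube-test bouts are rendered as nose/tailbase keypoint tracks in
  tube coordinates. Behavior kinematics are chosen so that the ethogram
  classifier's rule predicates hold on exactly the scripted frames: a
  pushing mouse advances nose and tailbase at 4 cm/s with the two noses
  0.4 cm apart, while the pushed partner's nose yields with the pusher and
  its tailbase gives ground at only 0.5 cm/s — below the retreat threshold,
  so the "partner could not retreat during the push" conjunct holds, and the
  partner's holding of ground makes a ``resist`` event true for it. A
  retreating mouse backs away at 3 cm/s. Between episodes mice glide back to
  their resting posts at 1.5 cm/s, below every threshold.
* Two-channel photometry: GCaMP6s-like transients (kernel
  (1 - e^(-t/rise)) * e^(-t/decay), peak-normalized on the sampling grid)
  appear only in the signal channel; a slow (<1 Hz) motion artifact is
  shared by both channels; both bleach with a common exponential and carry
  independent Gaussian noise.
* OFSI sessions: two 150 s trials of a confined random walk whose
  interaction-zone and corner-zone occupancies match the requested profile
  and whose zone-entry count is exact by construction.

Everything is reproducible from integer seeds: identical parameters and
seed give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.ndimage

from .ethogram import BehaviorEvent, KeypointTrack, TubeBout
from .ofsi import ArenaGeometry, ArenaTrajectory, Rect
from .photometry import PhotometryRecording

__all__ = [
    "Episode",
    "BoutScript",
    "PhotoSimParams",
    "OfsiProfile",
    "CohortAnimal",
    "CohortDataset",
    "ScriptError",
    "simulate_tube_bout",
    "random_bout_script",
    "simulate_photometry",
    "transient_kernel",
    "kernel_peak_time",
    "kernel_amplitude_fraction",
    "simulate_ofsi_session",
    "simulate_cohort",
    "simulate_amplitude_dataset",
]

# kinematic conventions of the bout renderer (cm/s and cm)
PUSH_SPEED = 4.0
YIELD_SPEED = 0.5
RETREAT_SPEED = 4.0
RETURN_SPEED = 1.5
CREEP_SPEED = 0.5  # final-approach speed of a nose returning toward its partner
CREEP_ZONE_CM = 1.4  # distance over which the returning nose creeps
NOSE_GAP = 0.4
BODY_LEN = 4.0
TUBE_Y = 1.5

EPISODE_LABELS = ("body_push", "nose_push", "resist", "retreat", "idle")


class ScriptError(ValueError):
    """Invalid bout script (overlap, bounds, or insufficient recovery gaps)."""


@dataclass(frozen=True)
class Episode:
    label: str
    actor: str  # "A" | "B"
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in EPISODE_LABELS:
            raise ScriptError(f"unknown episode label {self.label!r}")
        if self.actor not in ("A", "B"):
            raise ScriptError("actor must be 'A' or 'B'")
        if self.start_s < 0 or self.duration_s <= 0:
            raise ScriptError("episode times must be non-negative / positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class BoutScript:
    """Scripted tube bout: labeled episodes plus rendering parameters."""

    episodes: list
    fps: float = 30.0
    duration_s: float | None = None
    tube_length_cm: float = 30.0
    noise_sd_cm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.tube_length_cm <= 0:
            raise ScriptError("fps and tube length must be positive")
        if self.noise_sd_cm < 0:
            raise ScriptError("noise sd must be non-negative")
        self.episodes = sorted(self.episodes, key=lambda e: e.start_s)
        if self.duration_s is None:
            end = max((e.end_s for e in self.episodes), default=0.0)
            self.duration_s = end + 2.0
        for e in self.episodes:
            if e.end_s > self.duration_s + 1e-9:
                raise ScriptError("episode extends past the bout duration")
            if e.label == "retreat" and e.duration_s < 0.8:
                raise ScriptError(
                    "retreat episodes must last >= 0.8 s to accumulate the "
                    "minimum retreat distance at the scripted speed")
        # per-actor overlap is a hard validation error
        for actor in ("A", "B"):
            eps = [e for e in self.episodes if e.actor == actor]
            for e1, e2 in zip(eps, eps[1:]):
                if e2.start_s < e1.end_s:
                    raise ScriptError(
                        f"overlapping episodes for actor {actor}")
        # the kinematic model moves both mice in every non-idle episode and
        # needs the inter-episode gap for the sub-threshold return glides
        active = [e for e in self.episodes if e.label != "idle"]
        for e1, e2 in zip(active, active[1:]):
            need = episode_return_need(e1)
            if e2.start_s < e1.end_s + need:
                raise ScriptError(
                    "episodes too close: the return glide after "
                    f"{e1.label}@{e1.start_s:g}s needs {need:.2f} s")


def _max_offset(ep: Episode) -> float:
    if ep.label in ("body_push", "nose_push", "resist"):
        return PUSH_SPEED * ep.duration_s
    if ep.label == "retreat":
        return RETREAT_SPEED * ep.duration_s
    return 0.0


def episode_return_need(ep: Episode) -> float:
    """Seconds of quiet time the renderer needs after ``ep`` to restore the
    canonical posture: away-moving series glide back first at RETURN_SPEED,
    then the one nose displaced backward returns, creeping over the final
    CREEP_ZONE_CM at CREEP_SPEED so it is never both overlapping its
    partner's nose and moving near the push threshold."""
    off = _max_offset(ep)
    if off == 0.0:
        return 0.0
    t_away = off / RETURN_SPEED
    t_nose = (max(0.0, off - CREEP_ZONE_CM) / RETURN_SPEED
              + min(off, CREEP_ZONE_CM) / CREEP_SPEED)
    return t_away + t_nose


def _episode_velocities(ep: Episode) -> dict:
    """Per-series +x velocities (cm/s) during an episode.

    Series keys: a_nose, a_tail, b_nose, b_tail. ``dir`` is the actor's
    forward direction along x (+1 for A, -1 for B).
    """
    d = +1.0 if ep.actor == "A" else -1.0
    me, other = (("a_nose", "a_tail"), ("b_nose", "b_tail")) if ep.actor == "A" \
        else (("b_nose", "b_tail"), ("a_nose", "a_tail"))
    v = {k: 0.0 for k in ("a_nose", "a_tail", "b_nose", "b_tail")}
    if ep.label == "body_push":
        v[me[0]] = PUSH_SPEED * d
        v[me[1]] = PUSH_SPEED * d
        v[other[0]] = PUSH_SPEED * d
        v[other[1]] = YIELD_SPEED * d
    elif ep.label == "nose_push":
        v[me[0]] = PUSH_SPEED * d
        v[me[1]] = YIELD_SPEED * d
        v[other[0]] = PUSH_SPEED * d
        v[other[1]] = YIELD_SPEED * d
    elif ep.label == "retreat":
        v[me[0]] = -RETREAT_SPEED * d
        v[me[1]] = -RETREAT_SPEED * d
    elif ep.label == "resist":
        # the partner initiates a body push; the actor holds its ground
        v[other[0]] = PUSH_SPEED * (-d)
        v[other[1]] = PUSH_SPEED * (-d)
        v[me[0]] = PUSH_SPEED * (-d)
        v[me[1]] = 0.0
    return v


def _write_glide(arr: np.ndarray, f0: int, off: float, fps: float, n: int,
                 speeds: list) -> int:
    """Write a multi-segment return glide cancelling displacement ``off``.

    ``speeds`` lists (speed_cm_s, distance_cm) segments, traversed in order
    in the direction opposite ``off``; the last frame of each completed
    segment is trimmed so the glide lands exactly on the resting post.
    Returns the frame index after the glide."""
    f = f0
    s = -np.sign(off)
    for speed, dist in speeds:
        if dist <= 0.0:
            continue
        n_f = int(np.ceil(dist * fps / speed))
        g1 = min(f + n_f, n)
        arr[f:g1] = s * speed
        if g1 - f == n_f and g1 > f:
            resid = s * speed * n_f / fps - s * dist
            arr[g1 - 1] -= resid * fps
        f = g1
        if f >= n:
            break
    return f


def _truth_events(ep: Episode, fps: float) -> list[BehaviorEvent]:
    f0 = int(round(ep.start_s * fps))
    f1 = int(round(ep.end_s * fps))
    if ep.label == "idle" or f1 <= f0:
        return []
    partner = "B" if ep.actor == "A" else "A"
    events = [BehaviorEvent(label=ep.label if ep.label != "resist" else "resist",
                            actor=ep.actor, start_frame=f0, end_frame=f1, fps=fps)]
    if ep.label in ("body_push", "nose_push"):
        # the pushed partner yields below the retreat distance: it resists
        if YIELD_SPEED * ep.duration_s < 2.0:
            events.append(BehaviorEvent(label="resist", actor=partner,
                                        start_frame=f0, end_frame=f1, fps=fps))
    elif ep.label == "resist":
        events.append(BehaviorEvent(label="body_push", actor=partner,
                                    start_frame=f0, end_frame=f1, fps=fps))
    return events


def simulate_tube_bout(script: BoutScript) -> tuple[TubeBout, list[BehaviorEvent]]:
    """Render a scripted bout to keypoint tracks plus its true ethogram.

    Mouse A enters from the x0 end (facing +x), mouse B from the x1 end
    (facing -x). Truth events carry the exact scripted frame spans and
    include the partner events the kinematics imply (a pushed partner that
    holds its ground resists; a resisted partner is body-pushing).
    """
    fps = script.fps
    n = int(round(script.duration_s * fps))
    mid = script.tube_length_cm / 2.0
    base = {
        "a_nose": mid - NOSE_GAP / 2.0,
        "a_tail": mid - NOSE_GAP / 2.0 - BODY_LEN,
        "b_nose": mid + NOSE_GAP / 2.0,
        "b_tail": mid + NOSE_GAP / 2.0 + BODY_LEN,
    }
    vel = {k: np.zeros(n) for k in base}

    for ep in script.episodes:
        if ep.label == "idle":
            continue
        f0 = int(round(ep.start_s * fps))
        f1 = min(int(round(ep.end_s * fps)), n)
        ev = _episode_velocities(ep)
        for k, v in ev.items():
            vel[k][f0:f1] = v
        # staggered return glides: away-moving series first, then the one
        # nose displaced backward, which creeps over the final stretch so it
        # is never overlapping and near the push threshold at once
        offs = {k: v * (f1 - f0) / fps for k, v in ev.items() if v != 0.0}
        phase2 = None
        for k in ("a_nose", "b_nose"):
            off = offs.get(k, 0.0)
            if off != 0.0:
                facing = 1.0 if k.startswith("a") else -1.0
                if -np.sign(off) == facing:
                    phase2 = k
        p1_end = f1
        for k, off in offs.items():
            if k == phase2:
                continue
            end = _write_glide(vel[k], f1, off, fps, n,
                               [(RETURN_SPEED, abs(off))])
            p1_end = max(p1_end, end)
        if phase2 is not None:
            off = offs[phase2]
            d = abs(off)
            _write_glide(vel[phase2], p1_end, off, fps, n,
                         [(RETURN_SPEED, max(0.0, d - CREEP_ZONE_CM)),
                          (CREEP_SPEED, min(d, CREEP_ZONE_CM))])

    rng = np.random.default_rng(script.seed)
    pos = {k: base[k] + np.concatenate([[0.0], np.cumsum(v[:-1])]) / fps
           for k, v in vel.items()}
    noise = {k: rng.normal(0.0, script.noise_sd_cm, size=(n, 2))
             for k in ("a_nose", "a_tail", "b_nose", "b_tail")}

    def track(prefix: str, mouse_id: str, facing: int) -> KeypointTrack:
        nx = pos[f"{prefix}_nose"] + noise[f"{prefix}_nose"][:, 0]
        ny = TUBE_Y + noise[f"{prefix}_nose"][:, 1]
        tx = pos[f"{prefix}_tail"] + noise[f"{prefix}_tail"][:, 0]
        ty = TUBE_Y + noise[f"{prefix}_tail"][:, 1]
        return KeypointTrack(mouse_id=mouse_id, nose_x=nx, nose_y=ny,
                             tail_x=tx, tail_y=ty, fps=fps, facing=facing)

    bout = TubeBout(track_a=track("a", "A", +1), track_b=track("b", "B", -1),
                    tube_x0=0.0, tube_x1=script.tube_length_cm)
    truth: list[BehaviorEvent] = []
    for ep in script.episodes:
        truth.extend(_truth_events(ep, fps))
    truth.sort(key=lambda ev: (ev.start_frame, ev.actor, ev.label))
    return bout, truth


def random_bout_script(rng: np.random.Generator, duration_s: float = 25.0,
                       fps: float = 30.0, noise_sd_cm: float = 0.05,
                       labels: tuple = ("body_push", "nose_push",
                                        "resist", "retreat"),
                       p_labels: tuple | None = None) -> BoutScript:
    """Draw a feasible random script: episodes with durations in
    [0.8, 2.2] s, random actors/labels, and gaps long enough for the
    renderer's return glides."""
    episodes = []
    t = float(rng.uniform(0.8, 1.6))
    while True:
        dur = float(rng.uniform(0.8, 2.2))
        if t + dur > duration_s - 1.5:
            break
        label = str(rng.choice(labels, p=p_labels))
        actor = str(rng.choice(["A", "B"]))
        ep = Episode(label=label, actor=actor, start_s=round(t, 3),
                     duration_s=round(dur, 3))
        episodes.append(ep)
        t = ep.end_s + episode_return_need(ep) + float(rng.uniform(0.5, 1.5))
    return BoutScript(episodes=episodes, fps=fps, duration_s=duration_s,
                      noise_sd_cm=noise_sd_cm,
                      seed=int(rng.integers(0, 2**31 - 1)))


# --------------------------------------------------------------------------
# photometry


@dataclass(frozen=True)
class PhotoSimParams:
    """Two-channel photometry simulation parameters.

    Defaults emulate a GCaMP6s recording demodulated at 100 samples/s:
    0.2 s rise / 1.5 s decay transients, slow photobleaching, a shared
    sub-1 Hz motion artifact, and white measurement noise. ``noise_sd`` and
    ``artifact_amp`` are fractions of ``baseline_f0``.
    """

    fs_hz: float = 100.0
    transient_amp_dff: float = 0.05
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.5
    bleach_tau_s: float = 3000.0
    artifact_amp: float = 0.02
    artifact_tau_s: float = 2.0
    artifact_gain_ratio: float = 1.0
    noise_sd: float = 0.005
    baseline_f0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if min(self.rise_tau_s, self.decay_tau_s, self.bleach_tau_s) <= 0:
            raise ValueError("time constants must be positive")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.transient_amp_dff < 0:
            raise ValueError("transient_amp_dff must be non-negative")


def transient_kernel(t: np.ndarray, rise_tau_s: float,
                     decay_tau_s: float) -> np.ndarray:
    """Unnormalized transient kernel (1 - e^(-t/rise)) e^(-t/decay), 0 for t<0."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0.0,
                 (1.0 - np.exp(-np.maximum(t, 0.0) / rise_tau_s))
                 * np.exp(-np.maximum(t, 0.0) / decay_tau_s),
                 0.0)
    return k


def kernel_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Analytic peak time of the transient kernel."""
    return rise_tau_s * np.log(1.0 + decay_tau_s / rise_tau_s)


def kernel_amplitude_fraction(rise_tau_s: float = 0.2, decay_tau_s: float = 1.5,
                              window: tuple[float, float] = (0.0, 4.0)) -> float:
    """Closed-form mean of the peak-normalized kernel over ``window``.

    This is the expected event-locked mean amplitude per unit of true peak
    dF/F: a transient of peak ``a`` yields a [0, 4] s mean of
    a * kernel_amplitude_fraction(...).
    """
    tr, td = rise_tau_s, decay_tau_s
    ta = 1.0 / (1.0 / tr + 1.0 / td)
    lo, hi = window

    def integral(u: float) -> float:
        return (-td * np.exp(-u / td)) - (-ta * np.exp(-u / ta))

    area = integral(hi) - integral(lo)
    peak = transient_kernel(np.array([kernel_peak_time(tr, td)]), tr, td)[0]
    return float(area / peak / (hi - lo))


def simulate_photometry(event_times_s, params: PhotoSimParams,
                        duration_s: float, event_amps=None
                        ) -> tuple[PhotometryRecording, dict]:
    """Simulate a two-channel recording with transients at ``event_times_s``.

    signal  = F0 e^(-t/tau_b) (1 + sum of transients) + artifact + noise
    control = F0 e^(-t/tau_b) (1 + gain * artifact/F0) + independent noise

    Transients appear only in the signal channel; the slow artifact is
    shared. Per-event peak amplitudes default to ``params.transient_amp_dff``
    and may be overridden per event via ``event_amps`` (negative values are
    allowed there, for modeling event-locked dips). Each event's sampled
    kernel is normalized by its own grid maximum, so the true peak dF/F of
    event i is exactly its amplitude.

    Returns the recording and a truth dict with the per-event peaks, the
    artifact series, and the clean fractional transient sum ``clean_dff``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    events = np.asarray(list(event_times_s), dtype=float)
    if np.any((events < 0) | (events > duration_s)):
        raise ValueError("event times must lie within [0, duration]")
    if event_amps is None:
        amps = np.full(events.size, params.transient_amp_dff)
    else:
        amps = np.asarray(list(event_amps), dtype=float)
        if amps.size != events.size:
            raise ValueError("event_amps must match event_times_s")

    fs = params.fs_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(params.seed)

    s = np.zeros(n)
    for t_e, a in zip(events, amps):
        k = transient_kernel(t - t_e, params.rise_tau_s, params.decay_tau_s)
        peak = k.max()
        if peak > 0:
            s += a * k / peak

    if params.artifact_amp > 0:
        raw = rng.normal(0.0, 1.0, n)
        art = scipy.ndimage.gaussian_filter1d(raw, sigma=params.artifact_tau_s * fs,
                                              mode="reflect")
        sd = art.std()
        art = (art / sd if sd > 0 else art) * params.artifact_amp * params.baseline_f0
    else:
        art = np.zeros(n)

    bleach = (np.exp(-t / params.bleach_tau_s)
              if np.isfinite(params.bleach_tau_s) else np.ones(n))
    f0 = params.baseline_f0
    noise_abs = params.noise_sd * f0
    signal = f0 * bleach * (1.0 + s) + art + rng.normal(0.0, noise_abs, n)
    control = (f0 * bleach * (1.0 + params.artifact_gain_ratio * art / f0)
               + rng.normal(0.0, noise_abs, n))
    rec = PhotometryRecording(time_s=t, signal=signal, control=control, fs_hz=fs)
    truth = {"event_times_s": events, "event_peaks_dff": amps,
             "artifact": art, "clean_dff": s}
    return rec, truth


# --------------------------------------------------------------------------
# OFSI sessions and cohorts

TRIAL_S = 150.0  # 2.5 min of free exploration per trial
_TRAVEL_SPEED = 12.0  # cm/s
_ZONE_MARGIN = 2.0  # travel targets this far inside a zone
_WALK_MARGIN = 1.5  # confined-walk margin inside a zone
_WALK_STEP = 0.35  # cm per frame (random-walk step sd)


@dataclass(frozen=True)
class OfsiProfile:
    """Requested OFSI occupancy profile for one animal.

    ``interaction_s`` / ``corner_s`` give per-trial target zone durations
    (seconds, trials 1 and 2); ``n_entries`` is the trial-2 interaction-zone
    entry count (zero requested interaction time forces zero entries);
    ``entry_amp_dff`` is the mean event-locked transient peak at trial-2
    zone entries.
    """

    label: str  # avoider | approacher | control
    interaction_s: tuple[float, float] = (45.0, 55.0)
    corner_s: tuple[float, float] = (8.0, 10.0)
    n_entries: int = 6
    entry_amp_dff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 0:
            raise ValueError("n_entries must be non-negative")
        for trial in (0, 1):
            si, co = self.interaction_s[trial], self.corner_s[trial]
            if si < 0 or co < 0:
                raise ValueError("zone durations must be non-negative")
            if si + co > TRIAL_S:
                raise ValueError("requested zone times exceed the trial length")


def _split_dwell(rng: np.random.Generator, total: float, n: int) -> list[float]:
    if n <= 0 or total <= 0:
        return []
    w = rng.uniform(0.7, 1.3, n)
    return list(total * w / w.sum())


def _line(p0: np.ndarray, p1: np.ndarray, step: float) -> np.ndarray:
    dist = float(np.hypot(*(p1 - p0)))
    k = max(1, int(np.ceil(dist / step)))
    frac = np.arange(1, k + 1) / k
    return p0 + frac[:, None] * (p1 - p0)


def _confined_walk(rng: np.random.Generator, start: np.ndarray, rect: Rect,
                   n: int) -> np.ndarray:
    if n <= 0:
        return np.empty((0, 2))
    steps = rng.normal(0.0, _WALK_STEP, (n, 2))
    pts = start + np.cumsum(steps, axis=0)
    # reflect into the rectangle
    for dim, lo, hi in ((0, rect.x0, rect.x1), (1, rect.y0, rect.y1)):
        span = hi - lo
        x = np.mod(pts[:, dim] - lo, 2 * span)
        pts[:, dim] = lo + np.where(x > span, 2 * span - x, x)
    return pts


def _rand_point(rng: np.random.Generator, rect: Rect) -> np.ndarray:
    return np.array([rng.uniform(rect.x0, rect.x1),
                     rng.uniform(rect.y0, rect.y1)])


def _neutral_rect(geom: ArenaGeometry) -> Rect:
    iz = geom.interaction_zone
    c = geom.corner_zones[0]
    return Rect(2.0, c.y1 + 2.0, geom.width - 2.0, iz.y0 - 2.0)


def _trial_trajectory(rng: np.random.Generator, geom: ArenaGeometry,
                      fps: float, si_time: float, corner_time: float,
                      n_si_visits: int) -> tuple[np.ndarray, np.ndarray]:
    """Frame positions for one trial plus interaction-zone entry times."""
    n_total = int(round(TRIAL_S * fps))
    step = _TRAVEL_SPEED / fps
    neutral = _neutral_rect(geom)
    iz = geom.interaction_zone
    corners = geom.corner_zones

    visits: list[tuple[str, Rect, float]] = []
    if si_time > 0 and n_si_visits > 0:
        if si_time / n_si_visits < 0.5:
            raise ValueError("interaction time too small for the requested "
                             "number of entries (need >= 0.5 s per entry)")
        for d in _split_dwell(rng, si_time, n_si_visits):
            visits.append(("interaction", iz, d))
    if corner_time > 0:
        n_c = 2 if corner_time >= 2.0 else 1
        for i, d in enumerate(_split_dwell(rng, corner_time, n_c)):
            visits.append((f"corner_{i}", corners[i % 2], d))
    order = rng.permutation(len(visits))
    visits = [visits[i] for i in order]

    # rough frame budget check (dwell + generous travel allowance)
    travel_allow = (len(visits) + 1) * (geom.height / _TRAVEL_SPEED) * fps
    if sum(v[2] for v in visits) * fps + travel_allow > n_total:
        raise ValueError("infeasible occupancy request: zone times plus "
                         "travel exceed the trial length")

    chunks: list[np.ndarray] = []
    entry_frames: list[int] = []
    pos = _rand_point(rng, neutral.shrink(4.0))
    chunks.append(pos[None, :])
    n_used = 1
    exit_cost = int(np.ceil(_ZONE_MARGIN / step))  # est. in-zone exit frames

    n_gaps = len(visits) + 1
    dwell_frames_total = int(sum(round(v[2] * fps) for v in visits))
    neutral_budget = max(0, n_total - dwell_frames_total
                         - int(travel_allow))
    gap_frames = [int(g * fps) for g in
                  _split_dwell(rng, neutral_budget / fps, n_gaps)]

    def extend(pts: np.ndarray) -> None:
        nonlocal pos, n_used
        if pts.size:
            chunks.append(pts)
            pos = pts[-1]
            n_used += len(pts)

    for i, (name, rect, dwell) in enumerate(visits):
        # wander in the neutral band
        extend(_confined_walk(rng, pos, neutral, gap_frames[i]))
        # travel (corner trips route via a waypoint above the corner so the
        # path cannot clip the other corner zone)
        target = _rand_point(rng, rect.shrink(_ZONE_MARGIN))
        if name.startswith("corner"):
            waypoint = np.array([rect.center[0], neutral.y0 + 1.0])
            extend(_line(pos, waypoint, step))
        approach = _line(pos, target, step)
        inside_approach = int(rect.contains(approach[:, 0], approach[:, 1]).sum())
        extend(approach)
        # dwell inside, compensating for travel frames spent in the zone
        n_dwell = max(1, int(round(dwell * fps)) - inside_approach - exit_cost)
        extend(_confined_walk(rng, pos, rect.shrink(_WALK_MARGIN), n_dwell))
        # leave toward the neutral band
        out = _rand_point(rng, neutral.shrink(4.0))
        if name.startswith("corner"):
            waypoint = np.array([rect.center[0], neutral.y0 + 1.0])
            extend(_line(pos, waypoint, step))
            extend(_line(pos, out, step))
        else:
            extend(_line(pos, out, step))

    # fill the remainder with neutral wandering, then trim to the exact length
    remaining = n_total - n_used
    if remaining > 0:
        extend(_confined_walk(rng, pos, neutral, remaining))
    xy = np.concatenate(chunks, axis=0)[:n_total]
    if xy.shape[0] < n_total:  # pragma: no cover - budget check prevents this
        pad = np.repeat(xy[-1][None, :], n_total - xy.shape[0], axis=0)
        xy = np.concatenate([xy, pad], axis=0)

    inside = iz.contains(xy[:, 0], xy[:, 1])
    onsets = np.flatnonzero(np.diff(inside.astype(int)) == 1) + 1
    if inside[0]:
        onsets = np.concatenate([[0], onsets])
    expected = len([v for v in visits if v[0] == "interaction"])
    if onsets.size != expected:  # pragma: no cover - construction guarantee
        raise RuntimeError("trajectory construction produced an unexpected "
                           f"entry count ({onsets.size} != {expected})")
    return xy, onsets / fps


def simulate_ofsi_session(profile: OfsiProfile, geom: ArenaGeometry | None = None,
                          fps: float = 30.0
                          ) -> tuple[ArenaTrajectory, ArenaTrajectory, np.ndarray]:
    """Two-trial OFSI session realizing ``profile``; returns (trial-1
    trajectory, trial-2 trajectory, true trial-2 interaction-zone entry
    times). Trial-1 visit count is 2 (or fewer for small times); trial-2
    entries equal ``profile.n_entries`` exactly when interaction time > 0."""
    if geom is None:
        geom = ArenaGeometry()
    rng = np.random.default_rng(profile.seed)
    trajs = []
    entries2 = np.array([])
    for trial in (1, 2):
        si = profile.interaction_s[trial - 1]
        co = profile.corner_s[trial - 1]
        n_vis = (min(2, max(1, int(si // 10)) if si > 0 else 0) if trial == 1
                 else (profile.n_entries if si > 0 else 0))
        xy, entry_t = _trial_trajectory(rng, geom, fps, si, co, n_vis)
        t = np.arange(xy.shape[0]) / fps
        trajs.append(ArenaTrajectory(time_s=t, x_cm=xy[:, 0], y_cm=xy[:, 1],
                                     trial=trial, fps=fps,
                                     partner="none" if trial == 1 else "CD1"))
        if trial == 2:
            entries2 = entry_t
    return trajs[0], trajs[1], entries2


# --------------------------------------------------------------------------
# cohorts

GROUP_PROFILES = {
    # (interaction_s per trial, corner_s per trial, n_entries)
    "resilient": ((45.0, 60.0), (8.0, 8.0), 6),
    "control": ((45.0, 55.0), (8.0, 10.0), 6),
    "susceptible": ((45.0, 10.0), (10.0, 45.0), 3),
}
DEFAULT_AMP_EFFECT = {"resilient": 0.05, "susceptible": 0.01, "control": 0.0}
ANIMAL_AMP_SD = 0.005  # between-animal sd of the event-locked peak (dF/F)
EVENT_AMP_SD = 0.002  # within-animal event-to-event sd (dF/F)


@dataclass
class CohortAnimal:
    subject_id: str
    group: str
    traj1: ArenaTrajectory
    traj2: ArenaTrajectory
    entry_times_s: np.ndarray
    recording: PhotometryRecording
    true_event_amps: np.ndarray
    true_mean_amp: float


@dataclass
class CohortDataset:
    animals: list
    seed: int
    amp_effect: dict

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": a.subject_id, "group": a.group,
                              "n_entries": a.entry_times_s.size,
                              "true_mean_amp": a.true_mean_amp}
                             for a in self.animals])

    def hash(self) -> str:
        h = hashlib.sha256()
        for a in self.animals:
            for arr in (a.traj1.x_cm, a.traj1.y_cm, a.traj2.x_cm, a.traj2.y_cm,
                        a.entry_times_s, a.recording.signal,
                        a.recording.control, a.true_event_amps):
                if arr is not None:
                    h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def simulate_cohort(n_resilient: int, n_susceptible: int, n_control: int,
                    amp_effect: dict | None = None, seed: int = 0,
                    geom: ArenaGeometry | None = None, fps: float = 30.0,
                    photo_params: PhotoSimParams | None = None) -> CohortDataset:
    """Simulate an OFSI cohort: per-animal two-trial trajectories plus a
    trial-2 photometry recording with group-dependent entry-locked transient
    amplitudes and per-animal random amplitude offsets (for mixed-model
    testing). Ground-truth group labels and amplitudes are retained."""
    if min(n_resilient, n_susceptible, n_control) < 0:
        raise ValueError("cohort counts must be non-negative")
    if amp_effect is None:
        amp_effect = dict(DEFAULT_AMP_EFFECT)
    if geom is None:
        geom = ArenaGeometry()
    if photo_params is None:
        photo_params = PhotoSimParams()
    ss = np.random.SeedSequence(seed)
    animals: list[CohortAnimal] = []
    plan = ([("resilient", i) for i in range(n_resilient)]
            + [("susceptible", i) for i in range(n_susceptible)]
            + [("control", i) for i in range(n_control)])
    children = ss.spawn(len(plan))
    for (group, i), child in zip(plan, children):
        rng = np.random.default_rng(child)
        si, co, n_e = GROUP_PROFILES[group]
        jit = rng.uniform(0.9, 1.1, 4)
        profile = OfsiProfile(
            label=group,
            interaction_s=(si[0] * jit[0], si[1] * jit[1]),
            corner_s=(co[0] * jit[2], co[1] * jit[3]),
            n_entries=n_e,
            entry_amp_dff=max(amp_effect[group], 0.0),
            seed=int(rng.integers(0, 2**31 - 1)))
        t1, t2, entries = simulate_ofsi_session(profile, geom, fps)
        mean_amp = amp_effect[group] + rng.normal(0.0, ANIMAL_AMP_SD)
        amps = mean_amp + rng.normal(0.0, EVENT_AMP_SD, entries.size)
        params = replace(photo_params, seed=int(rng.integers(0, 2**31 - 1)))
        rec, _ = simulate_photometry(entries, params, TRIAL_S, event_amps=amps)
        sid = f"{group[:3]}{i:02d}"
        rec.mouse_id = sid
        t1.subject_id = t2.subject_id = sid
        animals.append(CohortAnimal(subject_id=sid, group=group, traj1=t1,
                                    traj2=t2, entry_times_s=entries,
                                    recording=rec, true_event_amps=amps,
                                    true_mean_amp=float(mean_amp)))
    return CohortDataset(animals=animals, seed=seed, amp_effect=amp_effect)


def simulate_amplitude_dataset(rng: np.random.Generator, delta: float = 0.04,
                               mouse_sd: float = 0.01, resid_sd: float = 0.01,
                               n_mice: int = 10, n_events: int = 8,
                               base: float = 0.0) -> pd.DataFrame:
    """Event-level amplitude table for mixed-model calibration studies: two
    groups of ``n_mice`` mice x ``n_events`` events, group means separated
    by ``delta``, mouse random intercepts (sd ``mouse_sd``) and residual
    noise (sd ``resid_sd``)."""
    rows = []
    for g, mean in (("treat", base + delta), ("ctrl", base)):
        for m in range(n_mice):
            intercept = rng.normal(0.0, mouse_sd)
            vals = mean + intercept + rng.normal(0.0, resid_sd, n_events)
            for v in vals:
                rows.append({"value": v, "mouse": f"{g}{m}", "group": g})
    return pd.DataFrame(rows)
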