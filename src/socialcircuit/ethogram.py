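"""Rule-based tube-test ethogram classification and hierarchy ranking.

Two mice meet in a narrow tube; each tries to force the other to back out.
From nose and tailbase keypoints (DeepLabCut-style tracking, calibrated to
cm) this module classifies four behaviors along the 1-D tube axis:

* ``retreat`` — tailbase velocity at or below a negative threshold while the
  mouse accumulates a minimum backward displacement over the epoch.
* ``body_push`` — nose AND tailbase velocities at or above a positive
  threshold, the two noses overlapping, and the partner not retreating
  during the push.
* ``nose_push`` — as body push but without the tailbase-velocity criterion
  (and not already a body push).
* ``resist`` — the partner satisfies a push predicate while this mouse holds
  its ground (absolute tailbase displacement over the partner's push epoch
  below the retreat distance). The source protocol names resist without
  defining it; this predicate is our documented interpretation.

Velocities are signed so that positive means toward the partner (each
track's ``facing`` gives its forward direction along the tube axis).
Numeric thresholds are conventions exposed in :class:`EthogramConfig`, not
values taken from any protocol.

Bout outcomes (the loser's tailbase exits the tube on its own entry side),
within-cage ranking by daily round-robin wins, and the four-consecutive-day
rank stability criterion live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KeypointTrack",
    "TubeBout",
    "EthogramConfig",
    "BehaviorEvent",
    "BoutQualityError",
    "compute_velocity",
    "classify_behaviors",
    "behavior_rates",
    "detect_win",
    "rank_cage",
    "HierarchyDay",
    "assess_stability",
    "events_to_frame",
]

logger = logging.getLogger(__name__)

LABELS = ("body_push", "nose_push", "resist", "retreat")


class BoutQualityError(ValueError):
    """Raised when a bout cannot be scored (e.g. untrackable keypoint gaps)."""


@dataclass
class KeypointTrack:
    """Per-frame nose and tailbase coordinates of one mouse, in cm."""

    mouse_id: str
    nose_x: np.ndarray
    nose_y: np.ndarray
    tail_x: np.ndarray
    tail_y: np.ndarray
    fps: float
    facing: int  # +1: partner lies toward +x; -1: toward -x
    nose_conf: np.ndarray | None = None
    tail_conf: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrs = [self.nose_x, self.nose_y, self.tail_x, self.tail_y]
        n = len(arrs[0])
        if any(len(a) != n for a in arrs):
            raise ValueError("keypoint series must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.facing not in (+1, -1):
            raise ValueError("facing must be +1 or -1")
        if self.nose_conf is None:
            self.nose_conf = np.ones(n)
        if self.tail_conf is None:
            self.tail_conf = np.ones(n)

    @property
    def n_frames(self) -> int:
        return len(self.nose_x)


@dataclass
class TubeBout:
    """One tube-test bout: both tracks plus tube geometry and metadata."""

    track_a: KeypointTrack
    track_b: KeypointTrack
    tube_x0: float = 0.0
    tube_x1: float = 30.0
    cage_id: str = ""
    day: int = 0
    bout_id: str = ""

    def __post_init__(self) -> None:
        if self.track_a.n_frames != self.track_b.n_frames:
            raise ValueError("both tracks must share the frame count")
        if self.track_a.fps != self.track_b.fps:
            raise ValueError("both tracks must share fps")
        if not self.tube_x0 < self.tube_x1:
            raise ValueError("tube span must satisfy x0 < x1")

    @property
    def fps(self) -> float:
        return self.track_a.fps

    @property
    def n_frames(self) -> int:
        return self.track_a.n_frames

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def track(self, mouse_id: str) -> KeypointTrack:
        for t in (self.track_a, self.track_b):
            if t.mouse_id == mouse_id:
                return t
        raise KeyError(mouse_id)


@dataclass(frozen=True)
class EthogramConfig:
    """Classifier thresholds and post-processing parameters.

    The velocity/distance thresholds are conventions (the scoring protocol
    this follows states only that thresholds exist); all are config-exposed.
    """

    v_push_cm_s: float = 2.0
    v_retreat_cm_s: float = -2.0
    d_min_retreat_cm: float = 2.0
    nose_overlap_cm: float = 1.0
    smooth_frames: int = 5
    min_event_s: float = 0.2
    merge_gap_s: float = 0.3
    confidence_min: float = 0.6
    win_margin_cm: float = 1.0
    max_gap_s: float = 1.0  # longest interpolable low-confidence gap

    def __post_init__(self) -> None:
        if self.v_push_cm_s <= 0 or self.v_retreat_cm_s >= 0:
            raise ValueError("push threshold must be > 0 and retreat < 0")
        if self.smooth_frames < 1 or self.smooth_frames % 2 == 0:
            raise ValueError("smooth_frames must be odd and >= 1")
        if min(self.d_min_retreat_cm, self.nose_overlap_cm, self.min_event_s,
               self.merge_gap_s, self.win_margin_cm) < 0:
            raise ValueError("windows and distances must be non-negative")


@dataclass(frozen=True)
class BehaviorEvent:
    """Labeled behavior interval; frames half-open [start_frame, end_frame)."""

    label: str
    actor: str
    start_frame: int
    end_frame: int
    fps: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.start_frame < self.end_frame:
            raise ValueError("event must satisfy start < end")

    @property
    def start_s(self) -> float:
        return self.start_frame / self.fps

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps


def _interpolate_low_confidence(x: np.ndarray, conf: np.ndarray,
                                config: EthogramConfig) -> np.ndarray:
    good = conf >= config.confidence_min
    if good.all():
        return x.astype(float)
    if not good.any():
        raise BoutQualityError("no frames above the confidence threshold")
    return np.interp(np.arange(x.size), np.flatnonzero(good), x[good])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of odd width ``w``; truncated at the edges."""
    if w == 1:
        return x.astype(float)
    return pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()


def _central_diff(x: np.ndarray, fps: float) -> np.ndarray:
    v = np.empty_like(x, dtype=float)
    v[1:-1] = (x[2:] - x[:-2]) * (fps / 2.0)
    v[0] = (x[1] - x[0]) * fps
    v[-1] = (x[-1] - x[-2]) * fps
    return v


def compute_velocity(track: KeypointTrack,
                     config: EthogramConfig = EthogramConfig()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Signed nose and tailbase velocities (cm/s), positive toward the partner.

    Low-confidence frames are linearly interpolated, positions smoothed by a
    centered moving average of width ``smooth_frames`` (truncated at edges),
    then differentiated by central differences and signed by ``facing``.
    Raises if the bout has a low-confidence gap longer than ``max_gap_s`` or
    is shorter than the smoothing window.
    """
    if track.n_frames <= config.smooth_frames:
        raise ValueError("track shorter than the smoothing window")
    max_gap_frames = int(round(config.max_gap_s * track.fps))
    for conf in (track.nose_conf, track.tail_conf):
        bad_runs = _runs(conf < config.confidence_min)
        if bad_runs and max(e - s for s, e in bad_runs) > max_gap_frames:
            raise BoutQualityError(
                f"{track.mouse_id}: low-confidence gap exceeds "
                f"{config.max_gap_s} s; bout not scoreable")
    nose = _interpolate_low_confidence(track.nose_x, track.nose_conf, config)
    tail = _interpolate_low_confidence(track.tail_x, track.tail_conf, config)
    nose = _smooth(nose, config.smooth_frames)
    tail = _smooth(tail, config.smooth_frames)
    v_nose = track.facing * _central_diff(nose, track.fps)
    v_tail = track.facing * _central_diff(tail, track.fps)
    return v_nose, v_tail


def _retreat_mask(track: KeypointTrack, v_tail: np.ndarray,
                  config: EthogramConfig) -> np.ndarray:
    """Frames belonging to retreat epochs: candidate runs where the tailbase
    velocity is at or below the threshold AND the run's net backward
    displacement reaches the minimum distance."""
    cand = v_tail <= config.v_retreat_cm_s
    mask = np.zeros_like(cand)
    for s, e in _runs(cand):
        # backward displacement over the run: movement opposite the partner
        # direction, from the first to the last frame of the run
        disp = -track.facing * (track.tail_x[e - 1] - track.tail_x[s])
        if disp >= config.d_min_retreat_cm:
            mask[s:e] = True
    return mask


def _postprocess(mask: np.ndarray, fps: float,
                 config: EthogramConfig) -> list[tuple[int, int]]:
    """Run-length encode ``mask``; merge runs separated by less than
    ``merge_gap_s``; drop runs shorter than ``min_event_s``."""
    runs = _runs(mask)
    if not runs:
        return []
    gap = config.merge_gap_s * fps
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = config.min_event_s * fps
    return [(s, e) for s, e in merged if (e - s) >= min_len]


def classify_behaviors(bout: TubeBout,
                       config: EthogramConfig = EthogramConfig()
                       ) -> list[BehaviorEvent]:
    """Classify body pushes, nose pushes, resists, and retreats for both mice.

    Frame-wise predicates (see module docstring) are evaluated for each
    mouse, contiguous true frames form epochs, epochs separated by less than
    ``merge_gap_s`` merge, and epochs shorter than ``min_event_s`` are
    dropped. Events are returned sorted by start frame.
    """
    ta, tb = bout.track_a, bout.track_b
    va_nose, va_tail = compute_velocity(ta, config)
    vb_nose, vb_tail = compute_velocity(tb, config)

    overlap = np.abs(ta.nose_x - tb.nose_x) <= config.nose_overlap_cm
    retreat = {ta.mouse_id: _retreat_mask(ta, va_tail, config),
               tb.mouse_id: _retreat_mask(tb, vb_tail, config)}

    vel = {ta.mouse_id: (va_nose, va_tail), tb.mouse_id: (vb_nose, vb_tail)}
    partner = {ta.mouse_id: tb.mouse_id, tb.mouse_id: ta.mouse_id}
    tracks = {ta.mouse_id: ta, tb.mouse_id: tb}

    body_push, nose_push = {}, {}
    for m in (ta.mouse_id, tb.mouse_id):
        v_nose, v_tail = vel[m]
        not_partner_retreat = ~retreat[partner[m]]
        bp = ((v_nose >= config.v_push_cm_s) & (v_tail >= config.v_push_cm_s)
              & overlap & not_partner_retreat)
        np_ = ((v_nose >= config.v_push_cm_s) & overlap
               & not_partner_retreat & ~bp)
        body_push[m], nose_push[m] = bp, np_

    resist = {}
    for m in (ta.mouse_id, tb.mouse_id):
        pm = partner[m]
        partner_push = body_push[pm] | nose_push[pm]
        mask = np.zeros_like(partner_push)
        tr = tracks[m]
        for s, e in _runs(partner_push):
            disp = abs(tr.tail_x[e - 1] - tr.tail_x[s])
            if disp < config.d_min_retreat_cm:
                mask[s:e] = True
        resist[m] = mask

    events: list[BehaviorEvent] = []
    per_label = {"body_push": body_push, "nose_push": nose_push,
                 "resist": resist, "retreat": retreat}
    for label, masks in per_label.items():
        for m, mask in masks.items():
            for s, e in _postprocess(mask, bout.fps, config):
                events.append(BehaviorEvent(label=label, actor=m,
                                            start_frame=s, end_frame=e,
                                            fps=bout.fps))
    events.sort(key=lambda ev: (ev.start_frame, ev.actor, ev.label))
    return events


def behavior_rates(events: list[BehaviorEvent], bout: TubeBout) -> pd.DataFrame:
    """Per-mouse behavior initiation rates (events per second of bout)."""
    if bout.duration_s <= 0:
        raise ValueError("bout duration must be positive")
    mice = [bout.track_a.mouse_id, bout.track_b.mouse_id]
    counts = {(m, lab): 0 for m in mice for lab in LABELS}
    for ev in events:
        counts[(ev.actor, ev.label)] += 1
    rows = [{"mouse_id": m, "label": lab, "count": counts[(m, lab)],
             "rate_per_s": counts[(m, lab)] / bout.duration_s}
            for m in mice for lab in LABELS]
    return pd.DataFrame(rows)


def detect_win(bout: TubeBout,
               config: EthogramConfig = EthogramConfig()) -> str | None:
    """Bout winner: a mouse loses when its tailbase exits the tube span on
    its own entry side by more than ``win_margin_cm`` while the partner's
    tailbase is still inside; the first such frame decides. Returns the
    winner's mouse_id, or None (including a simultaneous double exit)."""
    out = {}
    inside = {}
    for tr in (bout.track_a, bout.track_b):
        if tr.facing == +1:
            out[tr.mouse_id] = tr.tail_x < bout.tube_x0 - config.win_margin_cm
        else:
            out[tr.mouse_id] = tr.tail_x > bout.tube_x1 + config.win_margin_cm
        inside[tr.mouse_id] = ((tr.tail_x >= bout.tube_x0)
                               & (tr.tail_x <= bout.tube_x1))
    a, b = bout.track_a.mouse_id, bout.track_b.mouse_id
    lose_a = out[a] & inside[b]
    lose_b = out[b] & inside[a]
    fa = np.flatnonzero(lose_a)
    fb = np.flatnonzero(lose_b)
    ia = fa[0] if fa.size else None
    ib = fb[0] if fb.size else None
    if ia is None and ib is None:
        return None
    if ia is not None and ib is not None and ia == ib:
        logger.warning("bout %s: simultaneous exit at frame %d", bout.bout_id, ia)
        return None
    if ib is None or (ia is not None and ia < ib):
        return b  # A exited first -> B wins
    return a


@dataclass
class HierarchyDay:
    """Win counts and ranks for one cage-day of round-robin testing."""

    cage_id: str
    day: int
    wins: dict
    ranks: dict
    unresolved_ties: list
    complete_round_robin: bool


def rank_cage(outcomes: list[tuple[str, str]], mice: list[str] | None = None,
              cage_id: str = "", day: int = 0) -> HierarchyDay:
    """Rank cage mates by descending daily win count.

    ``outcomes`` lists (winner, loser) pairs, ideally a complete round robin
    (each pair once); incomplete round robins are allowed but flagged.
    Two-way ties are broken by the head-to-head outcome; remaining ties
    share a rank and are flagged unresolved.
    """
    if mice is None:
        mice = sorted({m for wl in outcomes for m in wl})
    wins = {m: 0 for m in mice}
    beat = set()
    seen_pairs = set()
    for w, l in outcomes:
        wins[w] += 1
        beat.add((w, l))
        seen_pairs.add(frozenset((w, l)))
    n = len(mice)
    complete = len(seen_pairs) == n * (n - 1) // 2
    if not complete:
        logger.warning("cage %s day %d: incomplete round robin", cage_id, day)

    order = sorted(mice, key=lambda m: -wins[m])
    ranks: dict = {}
    unresolved: list = []
    i = 0
    rank = 1
    while i < n:
        tied = [m for m in order if wins[m] == wins[order[i]]]
        if len(tied) == 1:
            ranks[tied[0]] = rank
        elif len(tied) == 2 and ((tied[0], tied[1]) in beat
                                 or (tied[1], tied[0]) in beat):
            first, second = ((tied[0], tied[1])
                             if (tied[0], tied[1]) in beat else (tied[1], tied[0]))
            ranks[first] = rank
            ranks[second] = rank + 1
        else:
            for m in tied:
                ranks[m] = rank
            unresolved.append(tuple(sorted(tied)))
        i += len(tied)
        rank += len(tied)
    return HierarchyDay(cage_id=cage_id, day=day, wins=wins, ranks=ranks,
                        unresolved_ties=unresolved,
                        complete_round_robin=complete)


def assess_stability(days: list[HierarchyDay], run_length: int = 4) -> int | None:
    """First day (1-based index into ``days``) from which ranks are identical
    for ``run_length`` consecutive days; None if no such day exists."""
    if not days:
        raise ValueError("need at least one day of rankings")
    members = set(days[0].ranks)
    for d in days[1:]:
        if set(d.ranks) != members:
            raise ValueError("cage membership differs across days")
    for i in range(len(days) - run_length + 1):
        ref = days[i].ranks
        if all(days[i + j].ranks == ref for j in range(1, run_length)):
            return i + 1
    return None


def events_to_frame(events: list[BehaviorEvent], bout_id: str = "") -> pd.DataFrame:
    """Tidy (BED-like) interval table for a bout's ethogram."""
    return pd.DataFrame(
        [{"bout_id": bout_id, "start_frame": ev.start_frame,
          "end_frame": ev.end_frame, "label": ev.label, "actor": ev.actor,
          "start_s": ev.start_s, "duration_s": ev.duration_s}
         for ev in events])
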