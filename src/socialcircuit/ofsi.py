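"""Open-field social interaction (OFSI) occupancy, avoidance scoring, and
related dominance-call utilities.

The two-trial OFSI task measures social avoidance after chronic social
defeat: trial 1 presents an empty perforated chamber at the far wall, trial 2
the same chamber holding a CD1 partner. Avoidance is summarized by a
composite of four cohort-z-scored occupancy measures:

* interaction-zone time ratio (trial 2 / trial 1), z-scored, sign-flipped
* corner-zone time ratio (trial 2 / trial 1), z-scored
* interaction-zone time in trial 2, z-scored, sign-flipped
* corner-zone time in trial 2, z-scored

so that a positive composite always indicates avoidance. Stressed animals
with composite > 0 are classified susceptible, < 0 resilient.

Zone membership uses the animal centroid with closed zone boundaries; an
entry is an outside-to-inside transition (a trajectory starting inside
counts as an entry at t = 0). The same entry detector serves subject entries
(OFSI) and partner entries (forced interaction task).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as scstats

__all__ = [
    "Rect",
    "ArenaGeometry",
    "ArenaTrajectory",
    "ZoneOccupancy",
    "AvoidanceResult",
    "compute_zone_occupancy",
    "detect_zone_entries",
    "social_avoidance_scores",
    "urine_marking_call",
    "concordance_table",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with closed boundaries."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def shrink(self, margin: float) -> "Rect":
        return Rect(self.x0 + margin, self.y0 + margin,
                    self.x1 - margin, self.y1 - margin)


@dataclass(frozen=True)
class ArenaGeometry:
    """Open-field arena with a chamber at the far (+y) wall.

    Defaults: 44 x 44 cm arena; 10 cm x 6.5 cm chamber footprint centered on
    the far wall; 14 cm (deep) x 24 cm (wide) interaction zone centered on
    the chamber; two 9 x 9 cm corner zones on the opposite wall.
    """

    width: float = 44.0
    height: float = 44.0
    chamber_w: float = 10.0
    chamber_d: float = 6.5
    zone_w: float = 24.0
    zone_d: float = 14.0
    corner: float = 9.0

    def __post_init__(self) -> None:
        if not (self.zone_w >= self.chamber_w and self.zone_d >= self.chamber_d):
            raise ValueError("interaction zone must contain the chamber footprint")
        iz = self.interaction_zone
        if iz.x0 < 0 or iz.x1 > self.width:
            raise ValueError("interaction zone exceeds arena bounds")

    @property
    def chamber(self) -> Rect:
        cx = self.width / 2.0
        return Rect(cx - self.chamber_w / 2, self.height - self.chamber_d,
                    cx + self.chamber_w / 2, self.height)

    @property
    def interaction_zone(self) -> Rect:
        # centered on the chamber footprint, clipped at the far wall
        cx = self.width / 2.0
        cyc = self.height - self.chamber_d / 2.0
        y1 = min(self.height, cyc + self.zone_d / 2.0)
        y0 = y1 - self.zone_d
        return Rect(cx - self.zone_w / 2, y0, cx + self.zone_w / 2, y1)

    @property
    def corner_zones(self) -> tuple[Rect, Rect]:
        c = self.corner
        return (Rect(0.0, 0.0, c, c),
                Rect(self.width - c, 0.0, self.width, c))


@dataclass
class ArenaTrajectory:
    """Centroid track for one trial (~150 s of free exploration)."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    trial: int = 1
    fps: float = 30.0
    subject_id: str = ""
    partner: str = "none"  # none | CD1 | novel_C57

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (self.time_s.size == self.x_cm.size == self.y_cm.size):
            raise ValueError("trajectory arrays must be equal length")

    @property
    def duration_s(self) -> float:
        return self.time_s.size / self.fps


@dataclass
class ZoneOccupancy:
    """Per-zone dwell time, entry counts/times, and total path length."""

    duration_s: dict
    n_entries: dict
    entry_times: dict
    total_distance_cm: float
    trial_duration_s: float


def _entries_from_mask(inside: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    if inside.size == 0:
        return np.array([])
    onsets = np.flatnonzero(np.diff(inside.astype(int)) == 1) + 1
    if inside[0]:
        onsets = np.concatenate([[0], onsets])
    return time_s[onsets]


def compute_zone_occupancy(traj: ArenaTrajectory,
                           geom: ArenaGeometry) -> ZoneOccupancy:
    """Frame-wise point-in-rectangle occupancy of the interaction and corner
    zones; duration = frames inside / fps; entries are outside-to-inside
    transitions (a start inside counts)."""
    if traj.time_s.size == 0:
        raise ValueError("empty trajectory")
    zones = {
        "interaction": geom.interaction_zone,
        "corner_left": geom.corner_zones[0],
        "corner_right": geom.corner_zones[1],
    }
    dur, cnt, times = {}, {}, {}
    for name, rect in zones.items():
        inside = rect.contains(traj.x_cm, traj.y_cm)
        dur[name] = float(inside.sum() / traj.fps)
        t = _entries_from_mask(inside, traj.time_s)
        times[name] = t
        cnt[name] = int(t.size)
    dur["corners"] = dur["corner_left"] + dur["corner_right"]
    cnt["corners"] = cnt["corner_left"] + cnt["corner_right"]
    times["corners"] = np.sort(np.concatenate([times["corner_left"],
                                               times["corner_right"]]))
    dist = float(np.sum(np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))))
    return ZoneOccupancy(dur, cnt, times, dist, traj.duration_s)


def detect_zone_entries(traj: ArenaTrajectory, zone: Rect) -> np.ndarray:
    """Onset times of outside-to-inside transitions into ``zone``."""
    inside = zone.contains(traj.x_cm, traj.y_cm)
    return _entries_from_mask(inside, traj.time_s)


@dataclass
class AvoidanceResult:
    subject_id: str
    z_si_ratio: float
    z_corner_ratio: float
    z_si_duration: float
    z_corner_duration: float
    composite: float
    label: str  # susceptible | resilient
    tie: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance in an avoidance-score component")
    return (v - v.mean()) / sd


def social_avoidance_scores(table: pd.DataFrame) -> list[AvoidanceResult]:
    """Composite social-avoidance score and susceptible/resilient labels.

    ``table`` needs one row per scored (stressed) animal with columns
    ``subject_id``, ``si_t1``, ``si_t2``, ``corner_t1``, ``corner_t2``
    (interaction-zone and summed corner-zone durations, s, trials 1 and 2).

    Components per animal: SI ratio t2/t1, corner ratio t2/t1, SI duration
    t2, corner duration t2, each z-scored across the scored cohort (ddof 1);
    the two SI components are sign-flipped so positive means avoidance.
    Composite = mean of the four; > 0 susceptible, < 0 resilient, == 0
    resilient with a tie flag. Animals with a zero trial-1 denominator are
    flagged excluded and left out of the z-normalization.
    """
    req = {"subject_id", "si_t1", "si_t2", "corner_t1", "corner_t2"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    df = table.reset_index(drop=True)
    ok = (df["si_t1"] > 0) & (df["corner_t1"] > 0)
    scored = df[ok]
    if len(scored) < 2:
        raise ValueError("need >= 2 scorable animals with nonzero trial-1 times")
    comp = pd.DataFrame({
        "r_si": scored["si_t2"] / scored["si_t1"],
        "r_c": scored["corner_t2"] / scored["corner_t1"],
        "d_si": scored["si_t2"].astype(float),
        "d_c": scored["corner_t2"].astype(float),
    })
    z = {k: _zscore(comp[k].to_numpy()) for k in comp.columns}
    composite = (-z["r_si"] + z["r_c"] - z["d_si"] + z["d_c"]) / 4.0

    results: list[AvoidanceResult] = []
    zi = {idx: i for i, idx in enumerate(scored.index)}
    for idx, row in df.iterrows():
        if idx not in zi:
            results.append(AvoidanceResult(
                subject_id=str(row["subject_id"]), z_si_ratio=np.nan,
                z_corner_ratio=np.nan, z_si_duration=np.nan,
                z_corner_duration=np.nan, composite=np.nan, label="",
                excluded=True, exclusion_reason="zero_trial1_denominator"))
            continue
        i = zi[idx]
        c = float(composite[i])
        results.append(AvoidanceResult(
            subject_id=str(row["subject_id"]),
            z_si_ratio=float(-z["r_si"][i]),
            z_corner_ratio=float(z["r_c"][i]),
            z_si_duration=float(-z["d_si"][i]),
            z_corner_duration=float(z["d_c"][i]),
            composite=c,
            label="susceptible" if c > 0 else "resilient",
            tie=(c == 0.0)))
    return results


def urine_marking_call(count_a: int, area_a: float, count_b: int,
                       area_b: float) -> str | None:
    """Territorial dominance call from urine deposits: a mouse is dominant
    only if it produced strictly more deposits over a strictly greater total
    area; otherwise the pair is undetermined (returns None)."""
    if min(count_a, count_b) < 0 or min(area_a, area_b) < 0:
        raise ValueError("counts and areas must be non-negative")
    if count_a > count_b and area_a > area_b:
        return "A"
    if count_b > count_a and area_b > area_a:
        return "B"
    return None


def concordance_table(tube_calls, urine_calls) -> tuple[np.ndarray, float, float]:
    """2x2 concordance of per-pair dominance calls (tube test vs urine
    marking) with a two-sided Fisher exact p.

    Each call names the dominant mouse of a pair ("A" or "B"); rows index
    the tube call, columns the urine call. Returns (table, odds_ratio, p).
    """
    tube = list(tube_calls)
    urine = list(urine_calls)
    if len(tube) != len(urine) or len(tube) == 0:
        raise ValueError("need paired calls for >= 1 pair")
    tab = np.zeros((2, 2), dtype=int)
    for t, u in zip(tube, urine):
        tab[0 if t == "A" else 1, 0 if u == "A" else 1] += 1
    odds, p = scstats.fisher_exact_2x2(tab)
    return tab, odds, p
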