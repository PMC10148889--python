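"""Fiber-photometry dF/F normalization, QC, and event-locked analysis.

Two normalizations are provided, matching the two recording configurations:

* ``isosbestic_normalize`` — for recordings with a calcium-independent
  405 nm control channel: the control is least-squares fit (affine) to the
  signal channel and dF/F = (signal - fit) / fit. Shared motion/bleaching
  structure present in both channels cancels.
* ``sliding_median_normalize`` — for single-channel (terminal) recordings:
  the running median over a 10 s (+/- 5 s) window is the baseline estimate
  and dF/F = (signal - median) / median. The median is robust to sparse
  transients occupying less than half the window.

dF/F is fractional everywhere in this module (1% dF/F == 0.01).

Recordings whose dF/F spread (95th minus 5th percentile) is below 1% are
flagged as QC failures (lack of signal variation, e.g. poor indicator
expression or fiber misplacement).

Event-locked analysis extracts per-event windows around behavior onsets,
shifts each by its pre-event baseline mean, and summarizes each event by the
mean amplitude over the 0-4 s post-onset window. Inclusion rules differ by
task mode: tube-test bouts must last longer than 15 s (handling confound);
open-field / forced-interaction events within 3 s of a prior event are
dropped (slow indicator dynamics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "PhotometryRecording",
    "NormalizedTrace",
    "WindowSpec",
    "EventLockedSet",
    "lowpass",
    "isosbestic_normalize",
    "sliding_median_normalize",
    "qc_spread",
    "extract_event_locked",
    "pre_post_change",
]

_UNIFORM_RTOL = 1e-6


@dataclass
class PhotometryRecording:
    """Raw two-channel photometry: 470 nm signal and optional 405 nm control."""

    time_s: np.ndarray
    signal: np.ndarray
    control: np.ndarray | None = None
    fs_hz: float = 0.0
    mouse_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.size < 2:
            raise ValueError("recording needs at least 2 samples")
        dt = np.diff(self.time_s)
        dt0 = dt.mean()
        if dt0 <= 0 or np.max(np.abs(dt - dt0)) > _UNIFORM_RTOL * max(abs(dt0), 1.0):
            raise ValueError("sampling must be uniform")
        if not self.fs_hz:
            self.fs_hz = 1.0 / dt0
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.shape != self.signal.shape:
                raise ValueError("control must match signal length")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class NormalizedTrace:
    """dF/F trace with its normalization method tag and QC verdict."""

    time_s: np.ndarray
    dff: np.ndarray
    method: str  # "isosbestic" | "sliding_median"
    fs_hz: float
    qc_pass: bool | None = None
    qc_spread: float | None = None


@dataclass(frozen=True)
class WindowSpec:
    """Per-task event-locking windows (seconds relative to behavior onset)."""

    mode: str
    baseline: tuple[float, float]
    trace: tuple[float, float]
    amplitude: tuple[float, float] = (0.0, 4.0)
    refractory_s: float | None = None
    min_bout_s: float | None = None

    @classmethod
    def tube(cls) -> "WindowSpec":
        """Tube-test windows: baseline the second before onset; bouts must
        exceed 15 s; no refractory rule."""
        return cls(mode="tube", baseline=(-1.0, 0.0), trace=(-1.0, 5.0),
                   amplitude=(0.0, 4.0), refractory_s=None, min_bout_s=15.0)

    @classmethod
    def ofsi(cls) -> "WindowSpec":
        """Post-defeat task windows: baseline [-1.5, -1.0] s; 3 s refractory."""
        return cls(mode="ofsi", baseline=(-1.5, -1.0), trace=(-1.5, 5.0),
                   amplitude=(0.0, 4.0), refractory_s=3.0, min_bout_s=None)

    def __post_init__(self) -> None:
        if not self.baseline[0] < self.baseline[1] <= 0.0:
            raise ValueError("baseline window must precede event onset")
        if not (self.trace[0] <= self.amplitude[0] < self.amplitude[1] <= self.trace[1]):
            raise ValueError("amplitude window must lie within the trace window")
        if not (self.trace[0] <= self.baseline[0] and self.baseline[1] <= self.trace[1]):
            raise ValueError("baseline window must lie within the trace window")


@dataclass
class EventLockedSet:
    """Baseline-shifted per-event traces plus per-event summaries.

    ``traces`` has one row per *included* event; ``events`` carries one row
    per input event with an ``included`` flag and an exclusion ``reason``
    (short_bout | refractory | window_out_of_range) where applicable.
    """

    rel_time_s: np.ndarray
    traces: np.ndarray
    events: pd.DataFrame
    spec: WindowSpec

    @property
    def amplitudes(self) -> np.ndarray:
        return self.events.loc[self.events.included, "amplitude"].to_numpy()

    def group_average(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise mean and s.e.m. across included events."""
        if self.traces.shape[0] == 0:
            raise ValueError("no included events")
        mean = self.traces.mean(axis=0)
        n = self.traces.shape[0]
        sem = self.traces.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        return mean, sem


def lowpass(recording: PhotometryRecording, corner_hz: float = 15.0) -> PhotometryRecording:
    """Zero-phase Butterworth low-pass of both channels (DC gain 1).

    Software replica of the acquisition-side 15 Hz corner filter.
    """
    if recording.fs_hz <= 2.0 * corner_hz:
        raise ValueError("sampling rate must exceed twice the corner frequency")
    sos = scipy.signal.butter(4, corner_hz, btype="low", fs=recording.fs_hz,
                              output="sos")
    sig = scipy.signal.sosfiltfilt(sos, recording.signal)
    ctl = (scipy.signal.sosfiltfilt(sos, recording.control)
           if recording.control is not None else None)
    return PhotometryRecording(recording.time_s.copy(), sig, ctl,
                               fs_hz=recording.fs_hz,
                               mouse_id=recording.mouse_id,
                               session_id=recording.session_id)


def isosbestic_normalize(recording: PhotometryRecording) -> NormalizedTrace:
    """Control-channel dF/F: fit a*control + b to the signal by least
    squares, then dF/F = (signal - fit) / fit elementwise."""
    if recording.control is None:
        raise ValueError("isosbestic normalization requires a control channel")
    c = recording.control
    s = recording.signal
    if np.ptp(c) == 0.0 or c.std() == 0.0:
        raise ValueError("control channel is constant; affine fit is degenerate")
    A = np.column_stack([c, np.ones_like(c)])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    fit = A @ coef
    bad = np.flatnonzero(fit <= 0.0)
    if bad.size:
        raise ValueError(f"fitted control is non-positive at sample index {bad[0]}")
    dff = (s - fit) / fit
    return NormalizedTrace(recording.time_s.copy(), dff, "isosbestic",
                           recording.fs_hz)


def sliding_median_normalize(recording: PhotometryRecording,
                             window_s: float = 10.0) -> NormalizedTrace:
    """Running-median dF/F: for each sample, the median of the signal over a
    +/- window_s/2 window (truncated at the recording edges) is subtracted
    and divided out."""
    s = recording.signal
    if recording.duration_s <= window_s:
        raise ValueError("recording must be longer than the median window")
    half = int(round(window_s / 2.0 * recording.fs_hz))
    w = 2 * half + 1
    med = (pd.Series(s).rolling(window=w, center=True, min_periods=1)
           .median().to_numpy())
    bad = np.flatnonzero(med <= 0.0)
    if bad.size:
        raise ValueError(f"sliding median is non-positive at sample index {bad[0]}")
    dff = (s - med) / med
    return NormalizedTrace(recording.time_s.copy(), dff, "sliding_median",
                           recording.fs_hz)


def qc_spread(trace: NormalizedTrace,
              threshold: float = 0.01) -> tuple[float, bool]:
    """Signal-variation QC: spread = P95(dff) - P5(dff) (linear-interpolation
    percentiles); recordings with spread below 1% dF/F (0.01) fail.

    Sets ``qc_spread``/``qc_pass`` on the trace and returns them.
    """
    if trace.dff.size == 0:
        raise ValueError("empty trace")
    p5, p95 = np.percentile(trace.dff, [5.0, 95.0])
    spread = float(p95 - p5)
    ok = spread >= threshold
    trace.qc_spread = spread
    trace.qc_pass = bool(ok)
    return spread, bool(ok)


def _as_events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        ev = events.copy()
    else:
        rows = []
        for e in events:
            if isinstance(e, dict):
                rows.append(dict(e))
            else:
                rows.append({"onset_s": float(e)})
        ev = pd.DataFrame(rows)
    if "onset_s" not in ev.columns:
        raise ValueError("events need an 'onset_s' column")
    return ev


def extract_event_locked(trace: NormalizedTrace, events,
                         spec: WindowSpec) -> EventLockedSet:
    """Extract baseline-shifted event windows and per-event mean amplitudes.

    ``events`` is a DataFrame (or list of dicts / onset floats) with at least
    ``onset_s``; optional columns: ``bout_duration_s`` (required for the tube
    15 s rule), plus any metadata (mouse, group, trial, label) carried
    through. The refractory rule compares each onset against the previous
    onset in the supplied list (per recording), regardless of whether that
    prior event was itself included.
    """
    ev = _as_events_frame(events)
    fs = trace.fs_hz
    n = trace.dff.size
    t0 = float(trace.time_s[0])

    lo_off = int(round(spec.trace[0] * fs))
    hi_off = int(round(spec.trace[1] * fs))
    rel = np.arange(lo_off, hi_off + 1) / fs
    base_mask = (rel >= spec.baseline[0] - 0.5 / fs) & (rel < spec.baseline[1] - 0.5 / fs) \
        if spec.baseline[1] < 0 else \
        (rel >= spec.baseline[0] - 0.5 / fs) & (rel <= spec.baseline[1] + 0.5 / fs)
    amp_mask = (rel >= spec.amplitude[0] - 0.5 / fs) & (rel <= spec.amplitude[1] + 0.5 / fs)

    ev = ev.sort_values("onset_s", kind="stable").reset_index(drop=True)
    included, reasons, amps = [], [], []
    rows = []
    prev_onset = -np.inf
    for _, e in ev.iterrows():
        onset = float(e["onset_s"])
        reason = ""
        if spec.min_bout_s is not None:
            dur = float(e.get("bout_duration_s", np.nan))
            if not np.isfinite(dur):
                raise ValueError("tube mode requires 'bout_duration_s' per event")
            if dur <= spec.min_bout_s:
                reason = "short_bout"
        if not reason and spec.refractory_s is not None:
            if onset - prev_onset < spec.refractory_s:
                reason = "refractory"
        if not reason:
            i0 = int(round((onset - t0) * fs))
            if i0 + lo_off < 0 or i0 + hi_off >= n:
                reason = "window_out_of_range"
        prev_onset = onset
        if reason:
            included.append(False)
            reasons.append(reason)
            amps.append(np.nan)
            continue
        seg = trace.dff[i0 + lo_off: i0 + hi_off + 1].astype(float)
        seg = seg - seg[base_mask].mean()
        rows.append(seg)
        included.append(True)
        reasons.append("")
        amps.append(float(seg[amp_mask].mean()))

    ev["included"] = included
    ev["reason"] = reasons
    ev["amplitude"] = amps
    traces = np.array(rows) if rows else np.empty((0, rel.size))
    if traces.shape[0] == 0:
        warnings.warn("no events passed the inclusion rules")
    return EventLockedSet(rel_time_s=rel, traces=traces, events=ev, spec=spec)


def pre_post_change(els: EventLockedSet,
                    pre: tuple[float, float] = (-1.0, 0.0),
                    post: tuple[float, float] = (0.0, 1.0)) -> pd.DataFrame:
    """Per-event mean over the pre window [-1, 0) s and post window [0, 1] s
    of the shifted traces. The paired test itself is delegated to
    :func:`socialcircuit.stats.paired_t`."""
    rel = els.rel_time_s
    fs = 1.0 / (rel[1] - rel[0])
    if rel[0] > pre[0] + 0.5 / fs or rel[-1] < post[1] - 0.5 / fs:
        raise ValueError("trace window does not cover the pre/post windows")
    pre_mask = (rel >= pre[0] - 0.5 / fs) & (rel < pre[1] - 0.5 / fs)
    post_mask = (rel >= post[0] - 0.5 / fs) & (rel <= post[1] + 0.5 / fs)
    pre_means = els.traces[:, pre_mask].mean(axis=1)
    post_means = els.traces[:, post_mask].mean(axis=1)
    out = els.events.loc[els.events.included, ["onset_s"]].reset_index(drop=True)
    out["pre_mean"] = pre_means
    out["post_mean"] = post_means
    out["change"] = post_means - pre_means
    return out
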