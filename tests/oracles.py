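"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately written as slow, literal Python (loops over
frames/samples, explicit enumeration) so it shares no code path with the
vectorized implementations it validates.
"""

from __future__ import annotations

import math

import numpy as np

from socialcircuit import ethogram as eth


# --------------------------------------------------------------------------
# frame-wise ethogram classifier


def _runs_loop(mask):
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def framewise_classifier_oracle(bout, config=eth.EthogramConfig()):
    """Per-frame predicate evaluation + run-length post-processing, in plain
    loops, mirroring the documented classification rules."""
    ta, tb = bout.track_a, bout.track_b
    va_n, va_t = eth.compute_velocity(ta, config)
    vb_n, vb_t = eth.compute_velocity(tb, config)
    n = bout.n_frames
    tracks = {"A": ta, "B": tb}
    vel = {"A": (va_n, va_t), "B": (vb_n, vb_t)}
    partner = {"A": "B", "B": "A"}

    overlap = [abs(ta.nose_x[i] - tb.nose_x[i]) <= config.nose_overlap_cm
               for i in range(n)]

    # retreat frames: candidate runs with sufficient backward displacement
    retreat = {}
    for m in ("A", "B"):
        tr = tracks[m]
        v_tail = vel[m][1]
        cand = [v_tail[i] <= config.v_retreat_cm_s for i in range(n)]
        mask = [False] * n
        for s, e in _runs_loop(cand):
            disp = -tr.facing * (tr.tail_x[e - 1] - tr.tail_x[s])
            if disp >= config.d_min_retreat_cm:
                for i in range(s, e):
                    mask[i] = True
        retreat[m] = mask

    body, nose = {}, {}
    for m in ("A", "B"):
        v_n, v_t = vel[m]
        p = partner[m]
        body[m] = [v_n[i] >= config.v_push_cm_s
                   and v_t[i] >= config.v_push_cm_s
                   and overlap[i] and not retreat[p][i] for i in range(n)]
        nose[m] = [v_n[i] >= config.v_push_cm_s and overlap[i]
                   and not retreat[p][i] and not body[m][i] for i in range(n)]

    resist = {}
    for m in ("A", "B"):
        p = partner[m]
        push_p = [body[p][i] or nose[p][i] for i in range(n)]
        mask = [False] * n
        tr = tracks[m]
        for s, e in _runs_loop(push_p):
            if abs(tr.tail_x[e - 1] - tr.tail_x[s]) < config.d_min_retreat_cm:
                for i in range(s, e):
                    mask[i] = True
        resist[m] = mask

    events = []
    for label, masks in (("body_push", body), ("nose_push", nose),
                         ("resist", resist), ("retreat", retreat)):
        for m in ("A", "B"):
            runs = _runs_loop(masks[m])
            merged = []
            for s, e in runs:
                if merged and s - merged[-1][1] < config.merge_gap_s * bout.fps:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            for s, e in merged:
                if e - s >= config.min_event_s * bout.fps:
                    events.append((label, m, s, e))
    events.sort(key=lambda x: (x[2], x[1], x[0]))
    return events


# --------------------------------------------------------------------------
# photometry


def brute_sliding_median(signal, fs_hz, window_s=10.0):
    """Per-sample median over a truncated +/- window_s/2 window."""
    half = int(round(window_s / 2.0 * fs_hz))
    out = np.empty(len(signal))
    for i in range(len(signal)):
        lo = max(0, i - half)
        hi = min(len(signal), i + half + 1)
        out[i] = np.median(signal[lo:hi])
    return out


def brute_percentile(values, q):
    """Linear-interpolation percentile computed from first principles."""
    xs = sorted(values)
    n = len(xs)
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    if lo == hi:
        return xs[lo]
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


# --------------------------------------------------------------------------
# statistics


def welch_oracle(a, b):
    """Welch t and df recomputed numerically via scipy (independent path)."""
    import scipy.stats as sps
    r = sps.ttest_ind(a, b, equal_var=False)
    return r.statistic, r.df, r.pvalue


def fisher_two_sided_enum(table):
    """Two-sided Fisher exact p by exhaustive enumeration over all tables
    with the observed margins, using log factorials."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(k):
        return math.lgamma(k + 1)

    def log_p(x):
        # hypergeometric probability of table [[x, r1-x], [c1-x, r2-c1+x]]
        return (log_fact(r1) + log_fact(r2) + log_fact(c1) + log_fact(n - c1)
                - log_fact(n) - log_fact(x) - log_fact(r1 - x)
                - log_fact(c1 - x) - log_fact(r2 - c1 + x))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_p(x))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


# published two-sided Grubbs critical values at alpha = 0.05
GRUBBS_CRIT_05 = {4: 1.481, 5: 1.715, 6: 1.887, 7: 2.020, 8: 2.126,
                  10: 2.290, 12: 2.412, 15: 2.549, 20: 2.709}
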