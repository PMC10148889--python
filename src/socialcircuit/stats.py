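"""Statistical procedures for trial-level behavioral and photometry comparisons.

The analyses in this package rest on a small set of procedures: Welch's
unpaired t test for bout-level rate comparisons, iterative Grubbs outlier
removal, Fisher's exact test for dominance-call concordance, Bonferroni
correction for post-hoc families, and a linear mixed-effects contrast for
event-level photometry amplitudes with mouse identity as a random intercept
(repeated events per mouse are not independent).

Closed-form statistics (Welch, Grubbs) are implemented directly from their
definitions; Fisher's exact test and mixed-model estimation are delegated to
scipy / statsmodels — the contract here is the model structure and the
degrees-of-freedom convention, not the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "WelchResult",
    "LmmResult",
    "welch_t",
    "paired_t",
    "grubbs_critical_value",
    "grubbs_filter",
    "fisher_exact_2x2",
    "bonferroni",
    "fit_group_lmm",
    "repeated_measures_anova",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class LmmResult:
    """Fixed-effect group contrast from a random-intercept model.

    ``df`` follows the residual convention ``n_obs - n_fixed_params``, which
    matches how integer-like dfs are conventionally reported for these
    event-level contrasts (e.g. 44 events, 2 groups -> df 42).
    """

    estimate: float
    se: float
    t: float
    df: float
    p: float
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups_random: int


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unpaired two-sample t test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("welch_t requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            # identical constant samples: no evidence of a difference
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        raise ValueError("zero variance in both samples")
    sa2n, sb2n = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa2n + sb2n)
    df = (sa2n + sb2n) ** 2 / (sa2n**2 / (na - 1) + sb2n**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def paired_t(pre: Sequence[float], post: Sequence[float]) -> WelchResult:
    """Paired t test on per-event (pre, post) means; two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired_t requires equal-length samples")
    d = post - pre
    n = d.size
    if n < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        return WelchResult(t=0.0 if d.mean() == 0 else np.inf, df=float(n - 1),
                           p=1.0 if d.mean() == 0 else 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return WelchResult(t=float(t), df=float(n - 1), p=float(p))


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2} (upper quantile).
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal at level ``alpha``.

    Repeatedly computes G = max|x - mean| / sd and removes the most extreme
    point while G exceeds the critical value, stopping when nothing exceeds
    it or only 3 points remain. Returns (retained, removed) in input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("grubbs_filter expects a 1-D sample")
    if x.size < 3:
        warnings.warn("grubbs_filter: n < 3, sample returned unchanged")
        return x.copy(), np.array([], dtype=float)
    keep = np.ones(x.size, dtype=bool)
    while keep.sum() > 3:
        cur = x[keep]
        sd = cur.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(cur - cur.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= grubbs_critical_value(cur.size, alpha):
            break
        keep[np.flatnonzero(keep)[i]] = False
    return x[keep], x[~keep]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    Returns (odds_ratio, p); p sums hypergeometric probabilities of tables
    (with fixed margins) no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("fisher_exact_2x2 requires non-negative integer cells")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p). ``m`` defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def fit_group_lmm(
    values: Sequence[float],
    mouse_ids: Sequence,
    groups: Sequence,
    contrast: tuple[str, str] | None = None,
) -> LmmResult:
    """Group contrast on event-level values with a random intercept per mouse.

    Model: value ~ group (fixed) + (1 | mouse) + residual, fit by REML via
    statsmodels MixedLM. ``contrast=(g1, g2)`` returns the g1 - g2 fixed
    effect; default is the first two group labels in sorted order.

    The reported df is n_obs - n_fixed_params and the p value comes from the
    t distribution at that df (see LmmResult).
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "mouse": np.asarray(mouse_ids).astype(str),
         "group": np.asarray(groups).astype(str)}
    )
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("fit_group_lmm requires at least 2 groups")
    for g in levels:
        if df.loc[df.group == g, "mouse"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 mice")
    if df["mouse"].nunique() < 2:
        raise ValueError("singular design: a single mouse overall")
    if contrast is None:
        contrast = (levels[1], levels[0])
    g1, g2 = contrast
    if g1 not in levels or g2 not in levels:
        raise ValueError(f"contrast groups must be among {levels}")
    # treatment coding with g2 as the reference level
    cats = [g2] + [g for g in levels if g != g2]
    df["group"] = pd.Categorical(df["group"], categories=cats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ group", df, groups=df["mouse"])
        res = None
        last_err: Exception | None = None
        for method in ("bfgs", "powell", "lbfgs", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        if res is None:
            raise RuntimeError(f"mixed-model fit failed: {last_err}")
    name = f"group[T.{g1}]"
    est = float(res.fe_params[name])
    se = float(res.bse[name])
    n = len(df)
    k = len(res.fe_params)
    dof = float(n - k)
    tval = est / se
    p = 2.0 * sps.t.sf(abs(tval), dof)
    return LmmResult(
        estimate=est,
        se=se,
        t=float(tval),
        df=dof,
        p=float(p),
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        n_obs=n,
        n_groups_random=int(df["mouse"].nunique()),
    )


def repeated_measures_anova(data: pd.DataFrame, dv: str, subject: str,
                            within: list[str]):
    """Thin delegation to statsmodels AnovaRM for repeated-measures designs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.stats.AnovaRM(data, depvar=dv, subject=subject,
                                within=within).fit()
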