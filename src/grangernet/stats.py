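"""Companion statistics: repeated-measures correlation, Kruskal-Wallis
with Bonferroni-corrected follow-ups, and mean +/- SEM summaries.

Repeated-measures correlation (rmcorr) estimates the common within-subject
linear association between two repeatedly measured quantities by the
analysis-of-covariance model y ~ subject + x (subject as a factor, one
shared slope), so between-subject level differences never masquerade as
correlation.  The coefficient is

    r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_error)),

with SS_x the sum of squares attributable to x after subject effects, and
its t-test has df = n_obs - n_subjects - 1 (balanced: N(k-1) - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["RmcorrResult", "rmcorr", "kruskal_wallis_bonferroni", "mean_sem"]


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures correlation outcome."""

    r_rm: float
    df: int
    p_value: float
    n_subjects: int
    n_obs: int
    slope: float
    conf_int: tuple[float, float] | None = None

    def __post_init__(self):
        if not -1.0 <= self.r_rm <= 1.0:
            raise ValueError("r_rm outside [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df != self.n_obs - self.n_subjects - 1:
            raise ValueError("df must equal n_obs - n_subjects - 1")


def rmcorr(x, y, subject, conf_level: float | None = None) -> RmcorrResult:
    """Repeated-measures correlation of paired values x, y grouped by subject.

    Parameters
    ----------
    x, y
        Paired finite measurements.
    subject
        Subject label per pair; at least 2 subjects with at least 2
        observations each.
    conf_level
        If given (e.g. 0.95), attach an approximate Fisher-z confidence
        interval for r_rm; it ignores the repeated-measures structure
        beyond the rmcorr df and is labeled approximate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subject = np.asarray(subject)
    if not (x.shape == y.shape == subject.shape) or x.ndim != 1:
        raise ValueError("x, y, subject must be 1-d and the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite value in x or y")
    labels, idx = np.unique(subject, return_inverse=True)
    n_sub = labels.size
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    counts = np.bincount(idx)
    if counts.min() < 2:
        raise ValueError(
            f"every subject needs >= 2 observations; subject "
            f"{labels[counts.argmin()]!r} has {counts.min()}"
        )
    n_obs = x.size
    df = n_obs - n_sub - 1
    if df < 3:
        raise ValueError(f"only {df} residual degrees of freedom (need >= 3)")

    # within-subject centering == absorbing the subject factor
    xc = x - np.bincount(idx, weights=x)[idx] / counts[idx]
    yc = y - np.bincount(idx, weights=y)[idx] / counts[idx]
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("x is constant within every subject; slope undefined")
    slope = float(xc @ yc) / sxx
    ss_measure = slope * slope * sxx            # SS removed by the common slope
    resid = yc - slope * xc
    ss_error = float(resid @ resid)
    denom = ss_measure + ss_error
    if denom == 0:
        raise ValueError("y is constant within every subject; correlation undefined")
    r = float(np.sign(slope) * np.sqrt(ss_measure / denom))

    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))

    ci = None
    if conf_level is not None:
        if abs(r) >= 1.0:
            ci = (r, r)
        else:
            z = np.arctanh(r)
            half = sps.norm.ppf(0.5 + conf_level / 2.0) / np.sqrt(max(df - 1, 1))
            ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return RmcorrResult(r_rm=r, df=df, p_value=p, n_subjects=n_sub,
                        n_obs=n_obs, slope=slope, conf_int=ci)


def kruskal_wallis_bonferroni(groups, n_comparisons: int | None = None):
    """Kruskal-Wallis H test plus Bonferroni-corrected pairwise follow-ups.

    The omnibus H statistic is computed from pooled ranks with the tie
    correction and referred to chi-square with k-1 df.  Follow-ups are
    two-sided Mann-Whitney U tests for every group pair, each p multiplied
    by ``n_comparisons`` (the Bonferroni family size) and capped at 1.

    ``n_comparisons`` defaults to the number of pairwise comparisons,
    k(k-1)/2, and is reported back so the family-size choice is explicit.

    Returns
    -------
    dict with keys ``H``, ``p_value``, ``df``, ``n_comparisons``, and
    ``pairwise`` — a list of ((i, j), raw_p, adjusted_p) per group pair.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [g.size for g in groups]
    if min(sizes) < 2:
        raise ValueError(f"every group needs >= 2 values; sizes are {sizes}")
    k = len(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1.0)) * h - 3.0 * (n + 1.0)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(((tie_counts ** 3 - tie_counts).sum())) / (n ** 3 - n)
    if correction == 0.0:
        # all values identical: no rank separation at all
        h, p_omni = 0.0, 1.0
    else:
        h /= correction
        p_omni = float(sps.chi2.sf(h, df=k - 1))

    if n_comparisons is None:
        n_comparisons = k * (k - 1) // 2
    pairwise = []
    for i, j in combinations(range(k), 2):
        if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
            raw = 1.0
        else:
            raw = float(sps.mannwhitneyu(groups[i], groups[j],
                                         alternative="two-sided").pvalue)
        pairwise.append(((i, j), raw, min(1.0, raw * n_comparisons)))
    return {
        "H": float(h),
        "p_value": p_omni,
        "df": k - 1,
        "n_comparisons": n_comparisons,
        "pairwise": pairwise,
    }


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (sample SD / sqrt(n))."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
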