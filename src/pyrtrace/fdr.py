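"""Multiple-testing control and group comparisons.

Implements the two-stage linear step-up false-discovery-rate procedure of
Benjamini, Krieger and Yekutieli (the "BKY" sharpened procedure): stage 1
runs the linear (Benjamini-Hochberg) step-up at level q' = q/(1+q) to
estimate the number of true nulls m - r1; if 0 < r1 < m, stage 2 reruns the
step-up at level q' * m / (m - r1).  Rejecting nothing (r1 = 0) or
everything (r1 = m) short-circuits stage 2.

Also provides the two-group fold-change summary (ratio of means with a
Student's t-test; pooled-variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = ["BKYResult", "FoldChangeResult", "bky_two_stage",
           "group_fold_change", "bh_step_up"]


@dataclass(frozen=True)
class BKYResult:
    rejected: np.ndarray          # bool per input p-value, input order
    threshold: float              # operative p-value cutoff
    stage1_rejections: int
    q: float
    adjusted: np.ndarray          # monotone step-up-adjusted values


@dataclass(frozen=True)
class FoldChangeResult:
    ratio: float                  # mean(b) / mean(a)
    t_statistic: float
    p_value: float


def bh_step_up(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up: boolean rejections, input order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = level * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= crit)[0]
    k = below[-1] + 1 if len(below) else 0
    rej = np.zeros(m, dtype=bool)
    rej[order[:k]] = True
    return rej


def bky_two_stage(p, q: float = 0.05) -> BKYResult:
    """Two-stage linear step-up FDR control at level q.

    Returns per-test rejection flags (input order), the operative p-value
    threshold, and step-up-adjusted values (the smallest q at the operative
    stage-2 level at which each test would be rejected, made monotone).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    q1 = q / (1.0 + q)
    stage1 = bh_step_up(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        rejected = stage1
        level = q1
    else:
        level = q1 * m / (m - r1)
        rejected = bh_step_up(p, level)
    # operative threshold: largest rejected p (0 if none)
    threshold = float(p[rejected].max()) if rejected.any() else 0.0
    # adjusted values at the operative level's effective null count
    m0 = m - r1 if 0 < r1 < m else m
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    raw = p * m0 / ranks * (1.0 + q)
    adj_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return BKYResult(rejected=rejected, threshold=threshold,
                     stage1_rejections=r1, q=q, adjusted=adjusted)


def group_fold_change(values_a, values_b,
                      equal_var: bool = True) -> FoldChangeResult:
    """mean(b)/mean(a) with a two-sided two-sample t-test.

    ``equal_var=True`` gives the classic pooled-variance Student's t-test;
    False gives Welch's unequal-variance form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.mean() == 0:
        raise ZeroDivisionError("reference group mean is zero")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("both groups constant and equal; p undefined")
        # constant but different groups: separation is certain
        return FoldChangeResult(ratio=float(b.mean() / a.mean()),
                                t_statistic=float(np.inf
                                                  * np.sign(b.mean()
                                                            - a.mean())),
                                p_value=0.0)
    t, pv = scipy.stats.ttest_ind(b, a, equal_var=equal_var)
    return FoldChangeResult(ratio=float(b.mean() / a.mean()),
                            t_statistic=float(t), p_value=float(pv))
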