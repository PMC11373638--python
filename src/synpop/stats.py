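"""Tukey HSD with compact letter display, shared by the simulator and the
genomic-prediction comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["tukey_hsd", "TukeyResult"]


@dataclass
class TukeyResult:
    """Group means, the honestly-significant-difference threshold, and the
    compact letter display.  Groups sharing a letter have means that differ
    by less than ``hsd``."""

    means: dict[str, float]
    mse: float
    df_error: int
    q_critical: float
    hsd: float
    letters: dict[str, str]
    n_harmonic: float
    alpha: float
    degenerate: bool = False


def _letters_from_intervals(names_sorted: list[str], means_sorted: np.ndarray,
                            hsd: float) -> dict[str, str]:
    k = len(names_sorted)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k:
            d = means_sorted[i] - means_sorted[j + 1]
            # exactly equal means always share a letter (covers the
            # degenerate zero-MSE case where hsd == 0)
            if d < hsd or d == 0.0:
                j += 1
            else:
                break
        intervals.append((i, j))
    # keep only maximal intervals
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    maximal = sorted(set(maximal))
    letters = {name: "" for name in names_sorted}
    for letter_idx, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + letter_idx)
        for g in range(lo, hi + 1):
            letters[names_sorted[g]] += ch
    return letters


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.001) -> TukeyResult:
    """All-pairwise group-mean comparison by Tukey's studentized-range test.

    ``HSD = q(1 - alpha, k, df_error) * sqrt(MSE / n_harmonic)`` with the MSE
    from a one-way ANOVA and the harmonic mean of the group sizes (the
    Tukey-Kramer convention for unbalanced groups).  Letters are assigned so
    that any two groups sharing a letter differ by less than HSD.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrs.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(arrs)
    ns = np.array([v.size for v in arrs.values()], dtype=float)
    means = {g: float(v.mean()) for g, v in arrs.items()}
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in arrs.values())
    df_error = int(ns.sum()) - k
    mse = ss_within / df_error
    n_harm = k / np.sum(1.0 / ns)
    degenerate = mse == 0.0
    if degenerate:
        warnings.warn("zero within-group variance in every group; HSD is 0",
                      stacklevel=2)
        q_crit = np.nan
        hsd = 0.0
    else:
        q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_error))
        hsd = q_crit * np.sqrt(mse / n_harm)
    names_sorted = sorted(means, key=lambda g: -means[g])
    means_sorted = np.array([means[g] for g in names_sorted])
    letters = _letters_from_intervals(names_sorted, means_sorted, hsd)
    return TukeyResult(
        means=means,
        mse=mse,
        df_error=df_error,
        q_critical=q_crit,
        hsd=float(hsd),
        letters=letters,
        n_harmonic=float(n_harm),
        alpha=alpha,
        degenerate=degenerate,
    )
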