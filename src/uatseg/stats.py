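"""Evaluation statistics: Dice scores and run-population comparisons.

Repeated training runs of each method form populations of test Dice scores
and convergence epochs. Populations are compared against the baseline with
the two-sided Mann-Whitney U test (exact enumeration for small tie-free
samples, normal approximation with tie correction otherwise) and Levene's
test for equality of variances (training-stability check). Comparison
tables report means, percent differences vs baseline and significance
stars (* p<0.05, ** p<0.01, *** p<0.001); box-plot summary statistics use
the conventional 1.5·IQR whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import cbook
from scipy import stats as sps

__all__ = [
    "RunPopulation",
    "dice",
    "mann_whitney",
    "levene_test",
    "significance_stars",
    "comparison_table",
    "boxplot_stats_table",
]

#: Largest combined sample size for which the exact (enumeration-based)
#: Mann-Whitney p-value is used when there are no ties.
EXACT_LIMIT = 12


@dataclass
class RunPopulation:
    """Per-method population of repeated runs."""

    label: str
    dice_values: list = field(default_factory=list)
    epoch_values: list = field(default_factory=list)

    def metric(self, name: str) -> np.ndarray:
        if name == "dice":
            return np.asarray(self.dice_values, dtype=np.float64)
        if name == "epochs":
            return np.asarray(self.epoch_values, dtype=np.float64)
        raise ValueError("metric must be 'dice' or 'epochs'")


def dice(pred_mask, truth) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two binary masks.

    Both masks empty -> 1 (perfect agreement on absence); one empty -> 0.
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _check_sample(x, name):
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size < 2:
        raise ValueError(f"sample {name!r} needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U test.

    Returns ``(u, p, mode)`` with ``u`` the smaller of the two directional U
    statistics. ``mode`` records whether the exact null distribution
    (combined n <= 12, no ties) or the tie-corrected normal approximation
    was used.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    exact = no_ties and combined.size <= EXACT_LIMIT
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(res.pvalue), method


def levene_test(a, b, center: str = "mean"):
    """Levene's test for equality of variances (mean-centered by default;
    ``center='median'`` gives the Brown-Forsythe variant).

    Returns ``(W, p)``. Raises when both groups have zero spread, where the
    statistic is undefined.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    centerfn = np.mean if center == "mean" else np.median
    za = np.abs(a - centerfn(a))
    zb = np.abs(b - centerfn(b))
    if np.all(za == 0) and np.all(zb == 0):
        raise ValueError("degenerate input: no within-group spread in either group")
    if np.ptp(za) == 0 and np.ptp(zb) == 0:
        # constant deviations in both groups: W degenerates to 0/0; equal
        # spreads mean no evidence against equality, unequal spreads are
        # perfectly separated
        if za[0] == zb[0]:
            return 0.0, 1.0
        return float("inf"), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        # W is +inf when deviations are constant within each group but differ
        # between groups (perfect spread separation)
        res = sps.levene(a, b, center=center)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def comparison_table(populations, metric: str = "dice",
                     baseline_label: str = "baseline") -> pd.DataFrame:
    """One row per non-baseline population: mean, median, percent difference
    vs the baseline mean, Mann-Whitney U and p, significance stars.

    For the epochs metric a negative percent difference means faster
    convergence.
    """
    pops = {p.label: p for p in populations}
    if baseline_label not in pops:
        raise ValueError(f"baseline population {baseline_label!r} is missing")
    base = pops[baseline_label].metric(metric)
    base_mean = float(np.mean(base))
    rows = []
    for label, pop in pops.items():
        if label == baseline_label:
            continue
        vals = pop.metric(metric)
        u, p, mode = mann_whitney(vals, base)
        mean = float(np.mean(vals))
        diff_pct = (100.0 * (mean - base_mean) / base_mean if base_mean != 0
                    else float("nan"))
        rows.append({
            "method": label,
            "n": int(vals.size),
            "mean": mean,
            "median": float(np.median(vals)),
            "baseline_mean": base_mean,
            "difference_pct": diff_pct,
            "u_statistic": u,
            "p_value": p,
            "p_mode": mode,
            "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


def boxplot_stats_table(populations, metric: str = "dice") -> pd.DataFrame:
    """Box-and-whisker summary per population (median, quartiles, whiskers
    at 1.5·IQR, outlier count)."""
    rows = []
    for pop in populations:
        vals = pop.metric(metric)
        st = cbook.boxplot_stats(vals, whis=1.5)[0]
        rows.append({
            "method": pop.label,
            "n": int(vals.size),
            "mean": float(np.mean(vals)),
            "median": st["med"],
            "q1": st["q1"],
            "q3": st["q3"],
            "whisker_low": st["whislo"],
            "whisker_high": st["whishi"],
            "n_outliers": len(st["fliers"]),
        })
    return pd.DataFrame(rows)
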