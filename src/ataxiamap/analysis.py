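"""Posterior summaries of the fitted disease-course model.

Turns retained MCMC draws into the quantities of clinical interest:
per-level duration (delta) summaries, linearity assessment via credible
intervals of delta differences, item progression speeds and their
variability, group-level dynamics of the individual parameters, and the
correlation between onset age and CAG repeat length.

All credible intervals are equal-tailed percentile intervals of the
posterior draws.  No multiplicity correction is applied across delta
pairs; the linearity flag is based on raw 95% intervals, which slightly
overstates evidence when many pairs are inspected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorSamples

__all__ = [
    "summarize_deltas",
    "test_linearity",
    "item_speeds",
    "group_dynamics",
    "cag_onset_correlation",
    "rate_ratio",
    "LinearityResult",
    "CorrelationResult",
]


def _ci(draws: np.ndarray, level: float = 0.95, axis: int = 0):
    tail = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [tail, 0.5, 1.0 - tail], axis=axis)
    return lo, med, hi


def summarize_deltas(samples: PosteriorSamples, min_draws: int = 100) -> pd.DataFrame:
    """Median and equal-tailed 95% credible bounds for every level duration.

    One row per (item, level): columns ``item``, ``level``, ``median``,
    ``ci_low``, ``ci_high`` (years).
    """
    if samples.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws")
    rows = []
    for k, item in enumerate(samples.item_names):
        draws = samples.deltas[k]
        lo, med, hi = _ci(draws)
        for l in range(draws.shape[1]):
            rows.append(
                {
                    "item": item,
                    "level": l + 1,
                    "median": med[l],
                    "ci_low": lo[l],
                    "ci_high": hi[l],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LinearityResult:
    """Linearity assessment of one item's progression.

    Progression is flagged nonlinear when the 95% credible interval of at
    least one pairwise delta difference excludes zero.  ``range_median`` /
    ``range_ci`` summarize the per-draw difference between the slowest and
    fastest level (the item's maximum difference in progression, years).
    """

    item: str
    nonlinear: bool
    range_median: float
    range_ci: tuple[float, float]
    pairwise: pd.DataFrame  # level_a, level_b, median, ci_low, ci_high, excludes_zero


def test_linearity(samples: PosteriorSamples, item: str | int) -> LinearityResult:
    """Credible-interval test of equal level durations within one item."""
    k = item if isinstance(item, int) else samples.item_names.index(item)
    draws = samples.deltas[k]
    n_levels = draws.shape[1]
    if n_levels < 2:
        raise ValueError("linearity requires an item with at least 2 deltas")
    rows = []
    any_excludes = False
    for a in range(n_levels):
        for b in range(a + 1, n_levels):
            diff = draws[:, b] - draws[:, a]
            lo, med, hi = _ci(diff)
            excludes = bool(lo > 0 or hi < 0)
            any_excludes = any_excludes or excludes
            rows.append(
                {
                    "level_a": a + 1,
                    "level_b": b + 1,
                    "median": med,
                    "ci_low": lo,
                    "ci_high": hi,
                    "excludes_zero": excludes,
                }
            )
    span = draws.max(axis=1) - draws.min(axis=1)
    lo, med, hi = _ci(span)
    return LinearityResult(
        item=samples.item_names[k],
        nonlinear=any_excludes,
        range_median=float(med),
        range_ci=(float(lo), float(hi)),
        pairwise=pd.DataFrame(rows),
    )


def item_speeds(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-item posterior of the mean delta (years per one-point increase).

    For each item the per-draw mean of its deltas is summarized by median,
    95% CI, and the IQR of the posterior (the variability measure).
    """
    rows = []
    for k, item in enumerate(samples.item_names):
        mean_draws = samples.deltas[k].mean(axis=1)
        lo, med, hi = _ci(mean_draws)
        q1, q3 = np.quantile(mean_draws, [0.25, 0.75])
        rows.append(
            {
                "item": item,
                "mean_delta_median": med,
                "ci_low": lo,
                "ci_high": hi,
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows)


def group_dynamics(
    samples: PosteriorSamples, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group posterior of the mean acceleration factor and mean onset age.

    ``grouping`` maps every subject id to a category (e.g. SCA type).  At
    each retained iteration the group means of exp(xi) and tau are computed;
    the result summarizes those per-iteration means by median and 95% CI.
    """
    ids = samples.subject_ids
    missing = [s for s in ids if s not in grouping]
    if missing:
        raise KeyError(f"{len(missing)} subjects missing from grouping, e.g. {missing[0]!r}")
    labels = np.array([grouping[s] for s in ids])
    rows = []
    for group in sorted(set(labels)):
        mask = labels == group
        if not mask.any():
            raise ValueError(f"empty group {group!r}")
        accel = np.exp(samples.xi[:, mask]).mean(axis=1)
        tau = samples.tau[:, mask].mean(axis=1)
        a_lo, a_med, a_hi = _ci(accel)
        t_lo, t_med, t_hi = _ci(tau)
        rows.append(
            {
                "group": group,
                "n_subjects": int(mask.sum()),
                "accel_median": a_med,
                "accel_ci_low": a_lo,
                "accel_ci_high": a_hi,
                "tau_median": t_med,
                "tau_ci_low": t_lo,
                "tau_ci_high": t_hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def cag_onset_correlation(
    tau_estimates: np.ndarray, cag: np.ndarray, ci_level: float = 0.95
) -> CorrelationResult:
    """Pearson correlation between onset age and log CAG repeat length.

    Pairs with a missing entry are dropped.  The confidence interval uses
    the Fisher z transform; the p-value is the two-sided test of r = 0.
    """
    tau = np.asarray(tau_estimates, dtype=float)
    cag_arr = np.asarray(cag, dtype=float)
    keep = ~(np.isnan(tau) | np.isnan(cag_arr))
    tau, cag_arr = tau[keep], cag_arr[keep]
    if len(tau) < 4:
        raise ValueError("need at least 4 complete (tau, CAG) pairs")
    if np.any(cag_arr <= 0):
        raise ValueError("CAG repeat lengths must be positive")
    log_cag = np.log(cag_arr)
    if np.ptp(tau) == 0 or np.ptp(log_cag) == 0:
        raise ValueError("zero variance in tau or log CAG")
    r, p = stats.pearsonr(tau, log_cag)
    n = len(tau)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(
        r=float(r), ci_low=float(lo), ci_high=float(hi), p_value=float(p), n=n
    )


def rate_ratio(fast_points_per_year: float, slow_points_per_year: float, ndigits: int = 2) -> float:
    """Ratio of two progression rates (points/year), rounded for reporting.

    E.g. 2.11 vs 0.8 points/year gives 2.64: the first group progresses
    2.64 times faster.
    """
    if slow_points_per_year <= 0:
        raise ValueError("rates must be positive")
    return round(fast_points_per_year / slow_points_per_year, ndigits)
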