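"""Expression-quartile dichotomization and survival comparison.

Splits a cohort into "low" (< 25th percentile) and "high" (>= 25th
percentile) expression arms, estimates Kaplan-Meier curves per arm,
compares them with a two-group log-rank test, and provides the exact
contingency test for binary response outcomes. The Wilcoxon rank-sum
comparison is shared with :mod:`cytomech.mtdyn`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mtdyn import compare_groups as rank_sum_compare  # noqa: F401  (shared contract)

__all__ = [
    "quartile_dichotomize",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "response_contingency",
    "rank_sum_compare",
    "cox_fit",
]


def quartile_dichotomize(expression: np.ndarray, percentile: float = 25.0) -> np.ndarray:
    """Label values "low" (< 25th percentile) or "high" (>= 25th).

    The percentile uses linear interpolation between order statistics.
    Ties at the threshold go to "high" (strict < for low). If all values
    are identical every subject is labeled high, with a warning.
    """
    values = np.asarray(expression, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to dichotomize by quartile")
    if np.all(values == values[0]):
        warnings.warn("all expression values identical: everything labeled high",
                      UserWarning, stacklevel=2)
        return np.full(values.shape, "high", dtype=object)
    threshold = np.percentile(values, percentile, method="linear")
    return np.where(values < threshold, "low", "high").astype(object)


@dataclass
class KMCurve:
    """Kaplan-Meier step function: survival probability after each event time."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray | None = None
) -> dict[str, KMCurve]:
    """Product-limit survival estimate, optionally per group.

    Returns a dict group label -> :class:`KMCurve`; with ``labels=None``
    all subjects form the single group ``"all"``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if labels is None:
        labels = np.full(times.shape, "all", dtype=object)
    labels = np.asarray(labels, dtype=object)
    out: dict[str, KMCurve] = {}
    for grp in pd.unique(labels):
        sel = labels == grp
        if not sel.any():
            continue
        t, e = times[sel], events[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t[e]) if e.any() else np.array([])
        surv = []
        s = 1.0
        for tj in uniq:
            at_risk = np.sum(t >= tj)
            deaths = np.sum((t == tj) & e)
            s *= 1.0 - deaths / at_risk
            surv.append(s)
        out[str(grp)] = KMCurve(times=uniq, survival=np.asarray(surv, dtype=float))
    return out


def logrank_test(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p), 1 df.

    Standard observed-minus-expected statistic with hypergeometric
    variance at each distinct event time; symmetric in group order. With
    no events at all, p = 1 is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels, dtype=object)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    if not events.any():
        warnings.warn("no events: log-rank undefined, returning p = 1",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    in1 = labels == groups[0]
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for tj in np.unique(times[events]):
        at_risk = times >= tj
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = (events & (times == tj)).sum()
        d1 = (events & (times == tj) & in1).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        warnings.warn("zero log-rank variance, returning p = 1", UserWarning, stacklevel=2)
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def response_contingency(
    response: np.ndarray, group: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """2×2 response-by-group table with Fisher's exact test.

    Returns ``(table, two_sided_p, conditional_odds_ratio)``. The p-value
    is the exact hypergeometric two-sided probability (sum over tables at
    most as probable as the observed one); the odds ratio is the
    conditional maximum-likelihood estimate. Zero margins are rejected.
    """
    response = np.asarray(response, dtype=bool)
    group = np.asarray(group, dtype=object)
    glabels = pd.unique(group)
    if len(glabels) != 2:
        raise ValueError("need exactly two group labels")
    table = np.array(
        [
            [np.sum(response & (group == g)), np.sum(~response & (group == g))]
            for g in sorted(map(str, glabels))
        ],
        dtype=int,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orres = stats.contingency.odds_ratio(table, kind="conditional")
    return table, float(p), float(orres.statistic)


def cox_fit(
    table: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
):
    """Thin pass-through to a standard Cox proportional-hazards fit.

    Delegates to :class:`lifelines.CoxPHFitter`; only the I/O is wrapped
    here (the model internals are deliberately not reimplemented). Returns
    the fitted lifelines object.
    """
    from lifelines import CoxPHFitter

    cols = [duration_col, event_col] + (covariate_cols or [])
    fitter = CoxPHFitter()
    fitter.fit(table[cols], duration_col=duration_col, event_col=event_col)
    return fitter
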