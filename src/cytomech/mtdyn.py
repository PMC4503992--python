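"""Microtubule length-trace statistics.

The core measurement is the maximum relative length change of a single
microtubule followed over a short movie:

    100 · (longest − shortest) / longest   [percent]

plus per-cell longest-MT aggregation and a Mann-Whitney / Wilcoxon
rank-sum group comparison (exact by enumeration for small samples, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MTLengthTrace",
    "max_length_change",
    "longest_mt_per_cell",
    "compare_groups",
    "EXACT_ENUMERATION_CUTOFF",
]

#: combined sample size up to which the Mann-Whitney p-value is computed
#: by full enumeration of group assignments
EXACT_ENUMERATION_CUTOFF = 12

#: frame count of the reference acquisition protocol (10 frames / 30 s)
REFERENCE_FRAME_COUNT = 10


@dataclass
class MTLengthTrace:
    """Length of one microtubule over consecutive frames.

    ``lengths`` are in µm (all positive, at least two frames);
    ``frame_interval`` in seconds.
    """

    cell_id: str
    mt_id: str
    lengths: np.ndarray
    frame_interval: float = 3.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1 or self.lengths.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        if not np.all(self.lengths > 0):
            raise ValueError("all lengths must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.lengths.size)

    @property
    def duration(self) -> float:
        """Time between first and last frame, seconds."""
        return (self.n_frames - 1) * self.frame_interval


def max_length_change(trace: MTLengthTrace) -> float:
    """Maximum length change of a trace, percent of the longest length.

    Warns (rather than errors) when the trace does not have the reference
    10 frames, since the statistic is defined for any trace length >= 2.
    """
    if trace.n_frames != REFERENCE_FRAME_COUNT:
        warnings.warn(
            f"trace has {trace.n_frames} frames (reference protocol is "
            f"{REFERENCE_FRAME_COUNT})",
            UserWarning,
            stacklevel=2,
        )
    longest = float(trace.lengths.max())
    shortest = float(trace.lengths.min())
    return 100.0 * (longest - shortest) / longest


def longest_mt_per_cell(traces: Iterable[MTLengthTrace]) -> dict[str, float]:
    """Per-cell longest MT length (µm): max over traces of per-trace maxima."""
    out: dict[str, float] = {}
    n = 0
    for tr in traces:
        n += 1
        peak = float(tr.lengths.max())
        out[tr.cell_id] = max(out.get(tr.cell_id, 0.0), peak)
    if n == 0:
        raise ValueError("no traces supplied")
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    For combined n <= ``EXACT_ENUMERATION_CUTOFF`` the p-value is computed
    by enumerating every assignment of the pooled values into two groups of
    the observed sizes and counting assignments whose U is at least as far
    from its null mean as the observed U. Larger samples use the normal
    approximation with tie correction. The p-value is symmetric in group
    order. If every pooled value is identical, p = 1 is returned with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups", UserWarning, stacklevel=2)
        return u_obs, 1.0
    n = pooled.size
    mu = a.size * b.size / 2.0
    if n <= EXACT_ENUMERATION_CUTOFF:
        idx = range(n)
        total = 0
        extreme = 0
        obs_dev = abs(u_obs - mu)
        for combo in itertools.combinations(idx, a.size):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def group_medians(groups: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Median per named group (convenience for cohort summaries)."""
    return {k: float(np.median(np.asarray(v, dtype=float))) for k, v in groups.items()}
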