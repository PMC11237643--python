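"""Structural-change segmentation of one-dimensional ordered series.

Sorted importance, abundance and coefficient-of-variation curves decay
roughly exponentially; a piecewise-constant least-squares segmentation cuts
such a curve into regimes with distinct means, and the first ("head")
segment defines the fingerprint set. The model within each segment is a
constant mean — the intercept-only case of the structural-change framework
— with a minimum admissible segment length of ``max(min_segment,
ceil(h * n))`` (defaults h = 0.01, min segment 2). The optimal breakpoints
for each candidate break count are found exactly by dynamic programming,
and the break count is selected by BIC over the segment residual sums of
squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

# Relative tolerance treating residual variation as numerically zero, and
# for calling two BIC values tied (ties resolve to fewer breaks).
_RSS_REL_TOL = 1e-12
_BIC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class Segmentation:
    """Result of a piecewise-constant segmentation.

    ``breakpoints`` holds, for every segment except the last, the exclusive
    end index of the segment: ``breakpoints == (3,)`` on a six-element
    series means segments ``values[:3]`` and ``values[3:]``.
    """

    breakpoints: tuple[int, ...]
    n_points: int
    min_segment_effective: int
    rss_by_breaks: dict = field(default_factory=dict)
    bic_by_breaks: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1


def _interval_cost_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cum = np.concatenate([[0.0], np.cumsum(values)])
    cum2 = np.concatenate([[0.0], np.cumsum(values**2)])
    return cum, cum2


def _cost(cum: np.ndarray, cum2: np.ndarray, i: np.ndarray | int, j: int):
    """Residual sum of squares of values[i:j] about their mean."""
    length = j - np.asarray(i)
    s = cum[j] - cum[i]
    s2 = cum2[j] - cum2[i]
    return s2 - s * s / length


def segment_series(
    values: Sequence[float],
    h: float = 0.01,
    min_segment: int = 2,
    max_breaks: int = 5,
) -> Segmentation:
    """Optimal piecewise-constant segmentation with BIC break-count choice.

    For each candidate number of breaks m = 0..max_breaks the globally
    RSS-optimal admissible segmentation is computed by dynamic programming;
    m is then chosen by ``BIC(m) = n log(RSS_m / n) + (2m + 2) log n``
    (m break positions, m+1 segment means, one variance). A series too
    short for any break yields zero breakpoints, which is not an error.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = len(y)
    if n < 2:
        raise ValueError("series must have at least two points")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite values")
    min_len = max(int(min_segment), math.ceil(h * n))
    feasible_breaks = min(max_breaks, n // min_len - 1)
    cum, cum2 = _interval_cost_arrays(y)

    scale = float(np.ptp(y)) or 1.0
    rss_floor = n * (scale * scale) * _RSS_REL_TOL

    rss0 = float(_cost(cum, cum2, 0, n))
    rss_by_breaks = {0: rss0}
    if feasible_breaks <= 0 or rss0 <= rss_floor:
        bic = {0: _bic(rss0, n, 0, rss_floor)}
        return Segmentation((), n, min_len, rss_by_breaks, bic)

    # best[m][j] = minimal RSS of y[:j] split into m+1 admissible segments
    best = np.full((feasible_breaks + 1, n + 1), np.inf)
    argmin = np.zeros((feasible_breaks + 1, n + 1), dtype=int)
    for j in range(min_len, n + 1):
        best[0, j] = _cost(cum, cum2, 0, j)
    for m in range(1, feasible_breaks + 1):
        # last segment [t, j) with t ranging over admissible prefix ends
        for j in range((m + 1) * min_len, n + 1):
            t = np.arange(m * min_len, j - min_len + 1)
            totals = best[m - 1, t] + _cost(cum, cum2, t, j)
            k = int(np.argmin(totals))
            best[m, j] = totals[k]
            argmin[m, j] = t[k]

    for m in range(1, feasible_breaks + 1):
        rss_by_breaks[m] = float(best[m, n])

    bic_by_breaks = {
        m: _bic(rss, n, m, rss_floor) for m, rss in rss_by_breaks.items()
    }
    chosen = 0
    for m in range(1, feasible_breaks + 1):
        if bic_by_breaks[m] < bic_by_breaks[chosen] - _BIC_TIE_TOL * (
            1.0 + abs(bic_by_breaks[chosen])
        ):
            chosen = m

    breaks: list[int] = []
    j = n
    for m in range(chosen, 0, -1):
        j = int(argmin[m, j])
        breaks.append(j)
    breaks.reverse()
    return Segmentation(tuple(breaks), n, min_len, rss_by_breaks, bic_by_breaks)


def _bic(rss: float, n: int, m: int, rss_floor: float) -> float:
    return n * math.log(max(rss, rss_floor) / n) + (2 * m + 2) * math.log(n)


def cut_head(labels: Sequence[str], segmentation: Segmentation) -> list[str]:
    """Labels of the first segment; empty (with a warning) if no breaks."""
    if len(labels) != segmentation.n_points:
        raise ValueError(
            f"{len(labels)} labels for a segmentation of "
            f"{segmentation.n_points} points"
        )
    if not segmentation.breakpoints:
        logger.warning("segmentation found no breakpoints; head set is empty")
        return []
    return list(labels[: segmentation.breakpoints[0]])


def cut_leading_segments(
    values: Sequence[float],
    labels: Sequence[str],
    segmentation: Segmentation,
    min_segment_mean: float,
) -> list[str]:
    """Labels of the maximal leading run of segments whose mean clears
    ``min_segment_mean``.

    Scaled importance curves are z-statistics: segments of uninformative
    attributes fluctuate in a noise band of roughly +/- 2 standard
    errors, so the signal set is every leading segment whose mean sits
    above that band, regardless of how many internal regimes the signal
    decay itself has. Empty (with a warning) if no segment qualifies or
    no breaks were found.
    """
    y = np.asarray(values, dtype=float)
    if len(labels) != segmentation.n_points or len(y) != segmentation.n_points:
        raise ValueError("labels/values length does not match the segmentation")
    if not segmentation.breakpoints:
        logger.warning("segmentation found no breakpoints; selected set is empty")
        return []
    bounds = [0, *segmentation.breakpoints, segmentation.n_points]
    cut = 0
    for start, end in zip(bounds[:-1], bounds[1:]):
        if y[start:end].mean() >= min_segment_mean:
            cut = end
        else:
            break
    if cut == 0:
        logger.warning(
            "no leading segment mean reaches %.2f; selected set is empty",
            min_segment_mean,
        )
    return list(labels[:cut])


class BreakpointSegmenter(BaseEstimator):
    """Estimator wrapper around :func:`segment_series`.

    Fitted attributes: ``breakpoints_``, ``n_segments_``, ``rss_by_breaks_``,
    ``bic_by_breaks_``, ``segmentation_``.
    """

    def __init__(self, h: float = 0.01, min_segment: int = 2, max_breaks: int = 5):
        self.h = h
        self.min_segment = min_segment
        self.max_breaks = max_breaks

    def fit(self, X, y=None):
        seg = segment_series(
            np.asarray(X, dtype=float).ravel(),
            h=self.h,
            min_segment=self.min_segment,
            max_breaks=self.max_breaks,
        )
        self.segmentation_ = seg
        self.breakpoints_ = seg.breakpoints
        self.n_segments_ = seg.n_segments
        self.rss_by_breaks_ = seg.rss_by_breaks
        self.bic_by_breaks_ = seg.bic_by_breaks
        return self

    def head(self, labels: Sequence[str]) -> list[str]:
        return cut_head(labels, self.segmentation_)
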