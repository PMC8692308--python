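"""RR-series preprocessing: artifact filtering, detrending, segmentation.

Three stages turn a raw beat-to-beat recording into the segments the
symbolic analysis consumes:

1. a running-median artifact filter (ectopic beats / dropped triggers),
2. smoothness-priors detrending — a second-difference-penalised least
   squares fit that removes slow non-stationary trends with a single
   regularisation parameter (default 500),
3. window selection: the first 5 minutes of a supine recording, or the
   most stationary 1000-beat window of a time-trial recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .series import RRSeries

__all__ = [
    "DetrendConfig",
    "SegmentSpec",
    "ArtifactReport",
    "filter_artifacts",
    "detrend_smoothness_priors",
    "select_supine_segment",
    "select_stationary_segment",
    "best_stationary_window",
    "stationarity_score",
]

logger = logging.getLogger(__name__)

TT_MOMENTS = ("beginning", "midway", "final")


@dataclass(frozen=True)
class DetrendConfig:
    """Smoothness-priors detrending configuration.

    ``lambda_`` is the regularisation parameter of the second-difference
    penalty (dimensionless; 500 by default, the value conventional for
    5-min HRV recordings).  Larger values leave more of the slow trend
    in the removed component.
    """

    lambda_: float = 500.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")


@dataclass(frozen=True)
class SegmentSpec:
    """Which analysis window to cut from a recording.

    ``kind='supine_5min'`` takes the beats spanning the first 300 s;
    ``kind='tt_moment'`` takes the most stationary run of ``length``
    beats (1000 by default) inside the beginning/midway/final third of
    the recording.  Indexing is 0-based, half-open.
    """

    kind: str  # 'supine_5min' | 'tt_moment'
    moment: str | None = None
    length: int = 1000
    duration_s: float = 300.0
    stride: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("supine_5min", "tt_moment"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "tt_moment":
            if self.moment not in TT_MOMENTS:
                raise ValueError(
                    f"tt_moment requires moment in {TT_MOMENTS}, got {self.moment!r}"
                )
        elif self.moment is not None:
            raise ValueError("moment is only meaningful for kind='tt_moment'")


@dataclass(frozen=True)
class ArtifactReport:
    flagged: np.ndarray  # indices of replaced beats
    n_flagged: int
    fraction: float


def filter_artifacts(
    series: RRSeries, threshold_fraction: float = 0.2
) -> tuple[RRSeries, ArtifactReport]:
    """Flag and impute artifactual beats by a local-median rule.

    Beat ``i`` is flagged when it deviates from the median of the
    five-beat neighbourhood ``RR[i-2..i+2]`` (truncated at the record
    edges) by more than ``threshold_fraction`` of that median; flagged
    beats are replaced by the local median.  More than 5% flagged logs a
    warning; more than 20% raises, since the segment is then unreliable.
    """
    n = len(series)
    if n < 5:
        raise ValueError("artifact filtering needs at least 5 beats")
    if threshold_fraction <= 0:
        raise ValueError("threshold_fraction must be positive")
    rr = series.intervals
    med = np.empty(n)
    # interior: vectorised 5-beat sliding median
    if n >= 5:
        windows = np.lib.stride_tricks.sliding_window_view(rr, 5)
        med[2 : n - 2] = np.median(windows, axis=1)
    for i in (0, 1, n - 2, n - 1):  # truncated edge windows
        lo, hi = max(i - 2, 0), min(i + 3, n)
        med[i] = np.median(rr[lo:hi])
    flagged = np.flatnonzero(np.abs(rr - med) > threshold_fraction * med)
    frac = flagged.size / n
    if frac > 0.20:
        raise ValueError(
            f"{frac:.1%} of beats flagged as artifacts (> 20%); segment rejected"
        )
    if frac > 0.05:
        logger.warning(
            "artifact filter: %.1f%% of beats flagged (subject=%s context=%s)",
            100 * frac, series.subject, series.context,
        )
    cleaned = rr.copy()
    cleaned[flagged] = med[flagged]
    out = RRSeries(
        cleaned,
        subject=series.subject,
        condition=series.condition,
        context=series.context,
    )
    return out, ArtifactReport(flagged=flagged, n_flagged=int(flagged.size),
                               fraction=float(frac))


def _second_difference_penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper-banded form of I + lam^2 * D2' D2 for `solveh_banded`.

    D2 is the (n-2)×n second-difference operator; the normal matrix is
    symmetric pentadiagonal.
    """
    l2 = lam * lam
    ab = np.zeros((3, n))
    # main diagonal of D2'D2: pattern 1, 5, 6, ..., 6, 5, 1
    d0 = np.full(n, 6.0)
    d0[0] = d0[-1] = 1.0
    if n > 1:
        d0[1] = d0[-2] = 5.0
    if n <= 2:
        d0[:] = 0.0
    elif n == 3:
        d0[:] = [1.0, 4.0, 1.0]
    elif n == 4:
        d0[:] = [1.0, 5.0, 5.0, 1.0]
    # first off-diagonal: -4 except -2 at both ends
    d1 = np.full(n - 1, -4.0)
    if n >= 3:
        d1[0] = d1[-1] = -2.0
    if n == 3:
        d1[:] = [-2.0, -2.0]
    # second off-diagonal: 1 everywhere
    d2 = np.ones(max(n - 2, 0))
    ab[2, :] = 1.0 + l2 * d0
    ab[1, 1:] = l2 * d1
    ab[0, 2:] = l2 * d2
    return ab


def detrend_smoothness_priors(
    values: np.ndarray, config: DetrendConfig = DetrendConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothness-priors detrending of an RR segment.

    Solves ``trend = argmin ||z - x||² + λ²||D₂x||²`` in closed form,
    ``trend = (I + λ² D₂ᵀD₂)⁻¹ z``, via a banded Cholesky solve (the
    normal matrix is symmetric positive-definite pentadiagonal), and
    returns ``(trend, z - trend)``.  λ = 0 reproduces the input exactly;
    any affine-in-index input lies in the penalty's null space and is
    removed entirely.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("need a 1-D segment of at least 3 values")
    lam = config.lambda_
    if lam == 0:
        return z.copy(), np.zeros_like(z)
    ab = _second_difference_penalty_banded(z.size, lam)
    trend = solveh_banded(ab, z, lower=False)
    return trend, z - trend


def select_supine_segment(
    series: RRSeries, duration_s: float = 300.0
) -> RRSeries:
    """Beats spanning the half-open window [0, duration_s) from the start.

    The first beat is at t = 0; a beat belongs to the window when its
    occurrence time is strictly below ``duration_s``.
    """
    if series.duration_s < duration_s:
        raise ValueError(
            f"recording spans {series.duration_s:.1f} s "
            f"< required {duration_s:.0f} s"
        )
    t = series.beat_times
    n_keep = int(np.searchsorted(t, duration_s, side="left"))
    return series.slice(0, n_keep)


def stationarity_score(window: np.ndarray, n_quarters: int = 4) -> float:
    """Heuristic non-stationarity score of a candidate window.

    The window is split into equal quarters; the score adds the worst
    quarter-mean drift (in window-SD units) and the worst relative
    quarter-SD change.  0 is perfectly stationary; a level shift or a
    variance change inside the window inflates it.
    """
    w = np.asarray(window, dtype=float)
    mu, sd = w.mean(), w.std(ddof=0)
    if sd < 1e-12:
        return 0.0
    quarters = np.array_split(w, n_quarters)
    mean_term = max(abs(q.mean() - mu) for q in quarters) / sd
    sd_term = max(abs(q.std(ddof=0) / sd - 1.0) for q in quarters)
    return float(mean_term + sd_term)


def best_stationary_window(
    values: np.ndarray, length: int = 1000, stride: int = 50
) -> tuple[int, float]:
    """Start index and score of the most stationary window of ``length``.

    Candidate starts are ``0, stride, 2·stride, …`` plus the last
    feasible start; ties go to the earliest start.
    """
    v = np.asarray(values, dtype=float)
    if v.size < length:
        raise ValueError(f"series of {v.size} beats has no {length}-beat window")
    starts = list(range(0, v.size - length + 1, stride))
    if starts[-1] != v.size - length:
        starts.append(v.size - length)
    best_start, best_score = starts[0], np.inf
    for s in starts:
        sc = stationarity_score(v[s : s + length])
        if sc < best_score - 1e-15:
            best_start, best_score = s, sc
    return best_start, float(best_score)


def select_stationary_segment(
    series: RRSeries, spec: SegmentSpec
) -> tuple[RRSeries, int, float]:
    """Most stationary ``spec.length``-beat window in the moment's third.

    The recording is split into thirds by beat count; within the
    designated third every candidate window at the configured stride is
    scored by :func:`stationarity_score` and the minimum-score window is
    returned together with its absolute start index and score.
    """
    if spec.kind != "tt_moment":
        raise ValueError("select_stationary_segment requires kind='tt_moment'")
    n = len(series)
    b1, b2 = n // 3, (2 * n) // 3
    bounds = {"beginning": (0, b1), "midway": (b1, b2), "final": (b2, n)}
    lo, hi = bounds[spec.moment]
    if hi - lo < spec.length:
        raise ValueError(
            f"the {spec.moment} third has {hi - lo} beats "
            f"< required {spec.length}"
        )
    rel_start, score = best_stationary_window(
        series.intervals[lo:hi], length=spec.length, stride=spec.stride
    )
    start = lo + rel_start
    return series.slice(start, start + spec.length), start, score
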