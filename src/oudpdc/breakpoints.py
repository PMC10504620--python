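"""Multiple mean-shift breakpoints in a monthly series, BIC-selected.

The model is a piecewise-constant mean: for a series ``y_1..y_T`` and break
boundaries ``0 < t_1 < ... < t_m < T`` (end-exclusive indices, so segment
``j`` is ``y[t_{j-1}:t_j]``), the fit minimizes the residual sum of squares
around segment means subject to a minimum segment length ``h``. The optimal
segmentation for each number of breaks ``m`` is found exactly by dynamic
programming over the last break position (constant-time segment costs from
prefix sums); the number of breaks is chosen by minimizing

    BIC(m) = T * ln(RSS_m / T) + [(m + 1) + m] * ln(T)

i.e. one parameter per segment mean plus one per break date, with the
residual variance concentrated out. Ties (including RSS = 0, where the BIC
is -inf) go to the smaller ``m``; among equal-cost segmentations the
lexicographically earliest break positions are returned.

Confidence intervals for the break dates come from a moving-block residual
bootstrap: residuals from the fitted step function are resampled in blocks,
added back to the fitted means, and the breaks re-estimated with ``m`` fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .pdc import MonthlySeries

__all__ = [
    "MeanShiftBreakpoints",
    "BreakpointResult",
    "SegmentCost",
    "optimal_breakpoints",
    "select_num_breaks",
    "breakpoint_confidence",
    "default_min_segment",
    "InfeasibleSegmentation",
]

_ATOL = 1e-9  # RSS tie tolerance for segmentation comparisons


class InfeasibleSegmentation(ValueError):
    """Requested breaks cannot fit: T < (m + 1) * h."""


def default_min_segment(T: int, trim: float = 0.15) -> int:
    """Conventional minimum segment length: max(2, ceil(trim * T))."""
    return max(2, int(np.ceil(trim * T)))


class SegmentCost:
    """Constant-time RSS of ``y[i:j]`` around its mean, via prefix sums."""

    def __init__(self, values: Sequence[float]):
        y = np.asarray(values, dtype=float)
        if y.ndim != 1:
            raise ValueError("series must be one-dimensional")
        self.n = len(y)
        self._s1 = np.concatenate([[0.0], np.cumsum(y)])
        self._s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def __call__(self, i: int, j: int) -> float:
        """RSS of the half-open slice ``y[i:j]``."""
        if not (0 <= i < j <= self.n):
            raise ValueError(f"invalid segment [{i}:{j}] for length {self.n}")
        n = j - i
        s = self._s1[j] - self._s1[i]
        ss = self._s2[j] - self._s2[i]
        return max(0.0, ss - s * s / n)

    def mean(self, i: int, j: int) -> float:
        return (self._s1[j] - self._s1[i]) / (j - i)


def _suffix_table(cost: SegmentCost, m_max: int, h: int) -> np.ndarray:
    """best[j, s] = min RSS of y[s:T] split into j+1 segments (each >= h)."""
    T = cost.n
    best = np.full((m_max + 1, T + 1), np.inf)
    for s in range(T - h, -1, -1):
        best[0, s] = cost(s, T)
    for j in range(1, m_max + 1):
        for s in range(T - (j + 1) * h, -1, -1):
            # first segment y[s:t], remainder split into j segments
            lo, hi = s + h, T - j * h
            vals = [cost(s, t) + best[j - 1, t] for t in range(lo, hi + 1)]
            if vals:
                best[j, s] = min(vals)
    return best


def _reconstruct(cost: SegmentCost, best: np.ndarray, m: int, h: int) -> tuple[int, ...]:
    """Lexicographically earliest optimal boundaries for exactly m breaks."""
    T = cost.n
    positions = []
    s, remaining = 0, m
    while remaining > 0:
        target = best[remaining, s]
        for t in range(s + h, T - remaining * h + 1):
            if cost(s, t) + best[remaining - 1, t] <= target + _ATOL:
                positions.append(t)
                s, remaining = t, remaining - 1
                break
        else:  # pragma: no cover - DP table guarantees a predecessor
            raise RuntimeError("breakpoint reconstruction failed")
    return tuple(positions)


def optimal_breakpoints(
    values: Sequence[float], m: int, h: int
) -> tuple[tuple[int, ...], float]:
    """Globally optimal placement of exactly ``m`` mean-shift breaks.

    Returns ``(boundaries, rss)`` where boundaries are end-exclusive indices
    (``t`` means the new regime starts at ``values[t]``; equivalently ``t``
    is the 1-based last index of the preceding segment). Raises
    :class:`InfeasibleSegmentation` when ``len(values) < (m + 1) * h``.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    cost = SegmentCost(values)
    if cost.n < (m + 1) * h:
        raise InfeasibleSegmentation(
            f"cannot place {m} break(s) with min segment {h} in length {cost.n}"
        )
    if m == 0:
        return (), cost(0, cost.n)
    best = _suffix_table(cost, m, h)
    return _reconstruct(cost, best, m, h), float(best[m, 0])


@dataclass
class BreakpointResult:
    """Fitted segmentation with model-selection and uncertainty detail.

    ``break_positions`` are end-exclusive boundary indices; when the input
    carried month labels, ``break_months`` holds the last month of each
    pre-break segment (a "July break" means July was the final month of the
    old regime; the new level takes effect the following month).
    """

    m_selected: int
    break_positions: tuple[int, ...]
    break_months: tuple[str, ...]
    segment_means: tuple[float, ...]
    rss_by_m: dict[int, float]
    bic_by_m: dict[int, float]
    ci_by_break: tuple[tuple[str, str], ...] = ()
    ci_index_by_break: tuple[tuple[int, int], ...] = ()
    warnings: tuple[str, ...] = ()
    h: int = 2
    months: tuple[str, ...] = field(default=(), repr=False)


def _bic(T: int, rss: float, m: int) -> float:
    if rss <= 0.0:
        return -np.inf
    return T * np.log(rss / T) + ((m + 1) + m) * np.log(T)


class MeanShiftBreakpoints(BaseEstimator):
    """Estimator for piecewise-constant mean shifts with BIC order selection.

    Parameters
    ----------
    m_max : int
        Largest number of breaks considered (clipped to feasibility).
    min_segment : int or None
        Minimum segment length ``h``; default ``max(2, ceil(0.15 T))``.
    n_boot : int
        Bootstrap replicates for break-date CIs (0 disables; < 50 records a
        warning on the result rather than failing).
    block_length : int
        Moving-block length for the residual bootstrap.
    random_state : int or None
        Seed for the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    result_ : BreakpointResult
    m_selected_, break_positions_, segment_means_, rss_by_m_, bic_by_m_,
    ci_by_break_ : convenience views of ``result_``.
    """

    def __init__(
        self,
        m_max: int = 5,
        min_segment: int | None = None,
        n_boot: int = 999,
        block_length: int = 3,
        random_state: int | None = None,
    ):
        self.m_max = m_max
        self.min_segment = min_segment
        self.n_boot = n_boot
        self.block_length = block_length
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def _series(self, X) -> tuple[np.ndarray, tuple[str, ...]]:
        if isinstance(X, MonthlySeries):
            return np.asarray(X.values, dtype=float), tuple(X.months)
        y = np.asarray(X, dtype=float)
        if y.ndim == 2 and y.shape[1] == 1:
            y = y[:, 0]
        if y.ndim != 1:
            raise ValueError("expected a 1-D series or a MonthlySeries")
        return y, ()

    def fit(self, X, y=None):
        """Fit on a :class:`MonthlySeries` or 1-D array of monthly means."""
        values, months = self._series(X)
        T = len(values)
        h = self.min_segment if self.min_segment is not None else default_min_segment(T)
        if T < h:
            raise InfeasibleSegmentation(f"series length {T} < min segment {h}")
        m_feasible = T // h - 1
        m_max = min(self.m_max, m_feasible)

        rss_by_m: dict[int, float] = {}
        pos_by_m: dict[int, tuple[int, ...]] = {}
        for m in range(m_max + 1):
            pos, rss = optimal_breakpoints(values, m, h)
            rss_by_m[m] = rss
            pos_by_m[m] = pos
        bic_by_m = {m: _bic(T, rss, m) for m, rss in rss_by_m.items()}
        m_sel = 0
        for m in sorted(bic_by_m):
            if bic_by_m[m] < bic_by_m[m_sel]:
                m_sel = m

        positions = pos_by_m[m_sel]
        cost = SegmentCost(values)
        bounds = (0, *positions, T)
        means = tuple(cost.mean(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        result = BreakpointResult(
            m_selected=m_sel,
            break_positions=positions,
            break_months=tuple(months[t - 1] for t in positions) if months else (),
            segment_means=means,
            rss_by_m=rss_by_m,
            bic_by_m=bic_by_m,
            h=h,
            months=months,
        )
        if self.n_boot and m_sel >= 1:
            warn = ()
            if self.n_boot < 50:
                warn = (f"n_boot={self.n_boot} < 50: CIs are unreliable",)
            ci_idx = _bootstrap_break_ci(
                values,
                positions,
                h=h,
                n_boot=self.n_boot,
                block_length=self.block_length,
                rng=np.random.default_rng(self.random_state),
            )
            result.ci_index_by_break = ci_idx
            if months:
                result.ci_by_break = tuple(
                    (months[lo - 1], months[hi - 1]) for lo, hi in ci_idx
                )
            result.warnings = warn
        self.result_ = result
        self.n_obs_ = T
        self.m_selected_ = result.m_selected
        self.break_positions_ = result.break_positions
        self.segment_means_ = result.segment_means
        self.rss_by_m_ = result.rss_by_m
        self.bic_by_m_ = result.bic_by_m
        self.ci_by_break_ = result.ci_by_break
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted step function over the training series."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        res = self.result_
        bounds = (0, *res.break_positions, self.n_obs_)
        y = np.empty(self.n_obs_)
        for a, b, mean in zip(bounds[:-1], bounds[1:], res.segment_means):
            y[a:b] = mean
        return y


def _fitted_step(values: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    bounds = (0, *positions, len(values))
    fitted = np.empty_like(values)
    for a, b in zip(bounds[:-1], bounds[1:]):
        fitted[a:b] = values[a:b].mean()
    return fitted


def _moving_block_resample(resid: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    T = len(resid)
    block = max(1, min(block, T))
    n_blocks = int(np.ceil(T / block))
    starts = rng.integers(0, T - block + 1, size=n_blocks)
    out = np.concatenate([resid[s : s + block] for s in starts])
    return out[:T]


def _bootstrap_break_ci(
    values: np.ndarray,
    positions: tuple[int, ...],
    h: int,
    n_boot: int,
    block_length: int,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], ...]:
    fitted = _fitted_step(values, positions)
    resid = values - fitted
    m = len(positions)
    boot = np.empty((n_boot, m), dtype=int)
    for b in range(n_boot):
        y_star = fitted + _moving_block_resample(resid, block_length, rng)
        pos_star, _ = optimal_breakpoints(y_star, m, h)
        boot[b] = pos_star
    lo = np.percentile(boot, 2.5, axis=0, method="nearest").astype(int)
    hi = np.percentile(boot, 97.5, axis=0, method="nearest").astype(int)
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))


# -- functional wrappers ----------------------------------------------------

def select_num_breaks(
    series: MonthlySeries | Sequence[float], m_max: int, h: int | None = None
) -> BreakpointResult:
    """BIC-select the number of breaks (no CIs); wrapper over the estimator."""
    est = MeanShiftBreakpoints(m_max=m_max, min_segment=h, n_boot=0)
    return est.fit(series).result_


def breakpoint_confidence(
    series: MonthlySeries | Sequence[float],
    result: BreakpointResult,
    n_boot: int = 999,
    block: int = 3,
    seed: int | None = None,
) -> BreakpointResult:
    """Attach moving-block bootstrap CIs to a fitted result (m fixed)."""
    if result.m_selected < 1:
        raise ValueError("confidence intervals require at least one break")
    values = (
        np.asarray(series.values, float)
        if isinstance(series, MonthlySeries)
        else np.asarray(series, float)
    )
    ci_idx = _bootstrap_break_ci(
        values,
        result.break_positions,
        h=result.h,
        n_boot=n_boot,
        block_length=block,
        rng=np.random.default_rng(seed),
    )
    result.ci_index_by_break = ci_idx
    if result.months:
        result.ci_by_break = tuple(
            (result.months[lo - 1], result.months[hi - 1]) for lo, hi in ci_idx
        )
    if n_boot < 50:
        result.warnings = result.warnings + (
            f"n_boot={n_boot} < 50: CIs are unreliable",
        )
    return result
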