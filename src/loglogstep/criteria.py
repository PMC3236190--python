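"""Step/plateau detection in log-log correlation curves and the three quality criteria.

The derivative of the log-log curve is taken as difference quotients between
consecutive samples.  A *step* shows up as a contiguous run of derivative
values above a height level; a *plateau* as samples below a (much smaller)
level.  Three weighted criteria quantify pattern visibility for a pattern of
length p:

(a) exactly **one** step at embedding dimension m = p (where all inter-cluster
    max-norm distances of an odd-length pattern coincide), with a surrogate
    comparison term when noise makes two or three steps reappear;
(b) exactly **p** steps at m = 1, where the p(p-1)/2 pairwise scalar cluster
    distances generically reduce to p distinct values for p = 3;
(c) plateau flatness at m = p compared with m = p - 1: the weighted count of
    below-level derivative samples at the lower dimension is subtracted from
    the count at the higher one, on the common radius span.

Scores are deterministic functions of the input curves and level/weight
vectors.  Across a parameter grid they are normalized by the observed grid
maximum (:func:`normalize_over_grid`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .correlation import CorrelationCurve

__all__ = [
    "DerivativeCurve",
    "LevelWeights",
    "QualityScores",
    "DEFAULT_PEAK_LEVELS",
    "DEFAULT_PLATEAU_LEVELS",
    "derivative",
    "count_peaks",
    "plateau_count",
    "criterion_a",
    "criterion_b",
    "criterion_c",
    "normalize_over_grid",
]


@dataclass(frozen=True, eq=False)
class DerivativeCurve:
    """Difference quotients of log10 C with respect to log10 eps, at bin midpoints."""

    log_eps_mid: np.ndarray
    slope: np.ndarray

    def __len__(self) -> int:
        return int(self.slope.size)


@dataclass(frozen=True)
class LevelWeights:
    """Three increasing height levels with positive quality weights."""

    levels: tuple[float, float, float]
    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        wt = tuple(float(x) for x in self.weights)
        if len(lv) != len(wt):
            raise ValueError("levels and weights must have equal length")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(x <= 0 for x in lv) or any(w <= 0 for w in wt):
            raise ValueError("levels and weights must be positive")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "weights", wt)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights))


#: Step-height levels (slope units) and weights for criteria (a) and (b):
#: sharper steps earn higher weight.
DEFAULT_PEAK_LEVELS = LevelWeights(levels=(0.5, 1.0, 2.0), weights=(1.0, 2.0, 3.0))
#: Below-levels and weights for plateau counting (criterion (c)): flatter
#: plateaus earn higher weight.  The levels sit well below typical step
#: slopes (>= 2 at moderate jitter) but at the scale of the smooth noise
#: background, so that genuinely flat stretches are rewarded without the
#: count collapsing to the saturation tail on contaminated data.
DEFAULT_PLATEAU_LEVELS = LevelWeights(levels=(0.25, 0.5, 1.0), weights=(3.0, 2.0, 1.0))


@dataclass(frozen=True)
class QualityScores:
    """The three criterion measures for one series/configuration."""

    q_a: float
    q_b: float
    q_c: float
    normalized: bool = False


def derivative(curve: CorrelationCurve) -> DerivativeCurve:
    """Difference-quotient derivative of the log-log curve."""
    if len(curve) < 2:
        raise ValueError("need at least two curve samples")
    d_eps = np.diff(curve.log_eps)
    if np.any(d_eps <= 0):
        raise ValueError("degenerate radius grid (non-increasing log_eps)")
    slope = np.diff(curve.log_C) / d_eps
    mid = 0.5 * (curve.log_eps[:-1] + curve.log_eps[1:])
    return DerivativeCurve(log_eps_mid=mid, slope=slope)


def count_peaks(deriv: DerivativeCurve, level: float) -> int:
    """Number of maximal contiguous runs of derivative samples strictly above ``level``."""
    if level <= 0:
        raise ValueError("level must be > 0")
    above = deriv.slope > level
    if not np.any(above):
        return 0
    starts = np.diff(above.astype(int), prepend=0) == 1
    return int(starts.sum())


def _span_mask(deriv: DerivativeCurve, span: Optional[tuple[float, float]]) -> np.ndarray:
    if span is None:
        return np.ones(len(deriv), dtype=bool)
    lo, hi = span
    return (deriv.log_eps_mid >= lo - 1e-12) & (deriv.log_eps_mid <= hi + 1e-12)


def plateau_count(
    deriv: DerivativeCurve,
    levels_weights: LevelWeights = DEFAULT_PLATEAU_LEVELS,
    span: Optional[tuple[float, float]] = None,
) -> float:
    """Weighted average, over the below-levels, of the count of derivative samples below each."""
    mask = _span_mask(deriv, span)
    slopes = deriv.slope[mask]
    counts = [float(np.sum(slopes < lv)) for lv in levels_weights.levels]
    return float(np.average(counts, weights=levels_weights.weights))


def _excess_peaks(counts: Sequence[int]) -> np.ndarray:
    """Pronouncedness of repeated steps per level: peak count minus one, clipped to [0, 2]."""
    return np.clip(np.asarray(counts, dtype=float) - 1.0, 0.0, 2.0)


def criterion_a(
    curve_at_p: CorrelationCurve,
    surrogate_curves: Sequence[CorrelationCurve],
    lw: LevelWeights = DEFAULT_PEAK_LEVELS,
) -> float:
    """Single-step visibility at m = p, with surrogate comparison.

    First term: each level whose derivative shows exactly one peak contributes
    its weight.  If two or three peaks are observed at some level (steps that
    should have vanished reappearing under noise), a second term measures the
    distance from the surrogate case: among the supplied permutation
    surrogates the one in which repeated steps emerge most pronouncedly is
    selected, and the (weighted, clipped) excess-peak pronouncedness of the
    series is subtracted from the surrogate's, level by level, scaled to at
    most one weight unit per level.
    """
    w = np.asarray(lw.weights)
    deriv = derivative(curve_at_p)
    counts = np.array([count_peaks(deriv, lv) for lv in lw.levels])
    score = float(np.sum(w[counts == 1]))

    repeated = (counts >= 2) & (counts <= 3)
    if not np.any(repeated):
        return score
    if not surrogate_curves:
        raise ValueError("surrogate curves are required when 2-3 peaks are observed")

    surr_counts = [
        np.array([count_peaks(derivative(c), lv) for lv in lw.levels]) for c in surrogate_curves
    ]
    # "most pronouncedly": the ensemble member with the largest weighted excess
    best = max(surr_counts, key=lambda c: float(np.sum(w * _excess_peaks(c))))
    diff = _excess_peaks(best) - _excess_peaks(counts)
    score += float(np.sum(w[repeated] * diff[repeated]) / 2.0)
    return score


def criterion_b(
    curve: CorrelationCurve,
    p: int,
    lw: LevelWeights = DEFAULT_PEAK_LEVELS,
) -> float:
    """Exactly-p-peaks visibility (evaluated at the configured dimension, default m = 1)."""
    if p < 2:
        raise ValueError("pattern length must be >= 2")
    deriv = derivative(curve)
    return float(
        sum(w for lv, w in zip(lw.levels, lw.weights) if count_peaks(deriv, lv) == p)
    )


def criterion_c(
    curve_hi: CorrelationCurve,
    curve_lo: CorrelationCurve,
    lw: LevelWeights = DEFAULT_PLATEAU_LEVELS,
) -> float:
    """Plateau-flatness difference between consecutive embedding dimensions.

    ``plateau_count(curve_hi) - plateau_count(curve_lo)`` with both derivative
    curves restricted to the intersection of their log-radius spans.
    """
    d_hi = derivative(curve_hi)
    d_lo = derivative(curve_lo)
    lo = max(d_hi.log_eps_mid[0], d_lo.log_eps_mid[0])
    hi = min(d_hi.log_eps_mid[-1], d_lo.log_eps_mid[-1])
    if hi <= lo:
        raise ValueError("curves have no overlapping radius span")
    span = (lo, hi)
    return plateau_count(d_hi, lw, span) - plateau_count(d_lo, lw, span)


def normalize_over_grid(raw_scores: np.ndarray) -> np.ndarray:
    """Divide a grid of raw scores by its maximum (which must be positive)."""
    arr = np.asarray(raw_scores, dtype=float)
    finite = arr[np.isfinite(arr)]
    top = finite.max() if finite.size else np.nan
    if not np.isfinite(top) or top <= 0:
        raise ValueError("normalization undefined: grid maximum is not positive")
    return arr / top
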