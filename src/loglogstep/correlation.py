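"""Delay-coordinate embedding and the correlation integral on a logarithmic radius grid.

The correlation integral C(eps) is estimated by averaging, over randomly
selected reference points, the fraction of all *other* embedded points within
max-norm distance eps (closed ball).  Points of a periodic interval series
fall into one cluster per cyclic shift of the pattern, so C(eps) rises in
sharp steps at the distinct inter-cluster distances; the log-log plot of
C(eps) is the object all downstream criteria work on.

Shot-noise guard: at radii supported by only a handful of counted pairs the
difference-quotient slope of log C is dominated by counting noise (for N
counted pairs the slope standard error is roughly sqrt(2)*0.434/(step*sqrt(N)),
i.e. ~0.4 slope units at N=1000 and the default step).  Curve samples with
C below ``c_floor`` are therefore dropped from the front of the curve; the
default 4e-4 corresponds to ~10^3 pairs at the recommended sampling depth
(10^4 points, 250 reference points).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .simulate import ISISeries

__all__ = [
    "EmbeddingConfig",
    "CorrelationConfig",
    "CorrelationCurve",
    "embed",
    "pair_distance",
    "build_eps_grid",
    "correlation_integral",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters: dimension ``m`` and delay (default 1)."""

    m: int
    delay: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")


@dataclass(frozen=True)
class CorrelationConfig:
    """Sampling parameters for the correlation-integral estimate.

    ``n_ref`` reference points are drawn without replacement; for 10^4
    embedded points something above 200 is recommended.

    The radius grid comes in two flavours.  The default ``grid="linear"``
    increases eps in ``n_eps`` equal increments up to the largest sampled
    distance (the increment scales with the data, so the log-log curve is
    covariant under time-unit rescaling); because the increments are linear,
    the shot-noise-dominated small-radius region collapses into a few wide
    log-bins and the steps of interest at pattern scale are finely resolved.
    ``grid="log"`` steps log10(eps) by ``log_eps_step`` from the smallest
    positive sampled distance instead.  ``c_floor`` is the minimum
    correlation value kept on the curve (shot-noise guard; 0 disables).
    """

    n_ref: int = 250
    grid: str = "linear"  # linear | log
    n_eps: int = 140
    log_eps_step: float = 0.05
    norm: str = "max"  # max | euclidean
    seed: int = 0
    c_floor: float = 4e-4

    def __post_init__(self) -> None:
        if self.n_ref < 1:
            raise ValueError("n_ref must be >= 1")
        if self.grid not in ("linear", "log"):
            raise ValueError(f"unknown grid mode {self.grid!r}")
        if self.n_eps < 2:
            raise ValueError("n_eps must be >= 2")
        if self.log_eps_step <= 0:
            raise ValueError("log_eps_step must be > 0")
        if self.norm not in ("max", "euclidean"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.c_floor < 0:
            raise ValueError("c_floor must be >= 0")


@dataclass(frozen=True, eq=False)
class CorrelationCurve:
    """Paired log10(eps) / log10(C) samples for one embedding dimension."""

    log_eps: np.ndarray
    log_C: np.ndarray
    m: int
    n_points: int

    def __post_init__(self) -> None:
        le = np.asarray(self.log_eps, dtype=float)
        lc = np.asarray(self.log_C, dtype=float)
        if le.shape != lc.shape or le.ndim != 1 or le.size < 1:
            raise ValueError("log_eps and log_C must be matching 1-d arrays")
        object.__setattr__(self, "log_eps", le)
        object.__setattr__(self, "log_C", lc)

    def __len__(self) -> int:
        return int(self.log_eps.size)


def embed(series: Union[ISISeries, np.ndarray], config: EmbeddingConfig) -> np.ndarray:
    """Coordinate-delay embedding: point i = (x_i, x_{i+d}, ..., x_{i+(m-1)d}).

    Returns an ``(N - (m-1)*delay, m)`` array.
    """
    x = series.intervals if isinstance(series, ISISeries) else np.asarray(series, dtype=float)
    m, d = config.m, config.delay
    n = x.size - (m - 1) * d
    if n < 2:
        raise ValueError(
            f"series of length {x.size} too short for embedding (m={m}, delay={d})"
        )
    idx = np.arange(n)[:, None] + d * np.arange(m)[None, :]
    return x[idx]


def pair_distance(x: np.ndarray, y: np.ndarray, norm: str = "max") -> float:
    """Distance between two embedded points (max norm by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("points must have equal dimension")
    diff = np.abs(x - y)
    if norm == "max":
        return float(diff.max())
    if norm == "euclidean":
        return float(np.sqrt(np.sum(diff**2)))
    raise ValueError(f"unknown norm {norm!r}")


def _ref_distances(points: np.ndarray, config: CorrelationConfig) -> tuple[np.ndarray, int]:
    """Distances from sampled reference points to all points (self-pairs included).

    Returns the flattened distance array and the number of reference points;
    the caller removes the ``n_ref`` zero self-distances from the counts.
    """
    n = points.shape[0]
    rng = np.random.default_rng(config.seed)
    if config.n_ref >= n:
        ref_idx = np.arange(n)
    else:
        ref_idx = rng.choice(n, size=config.n_ref, replace=False)
    m = points.shape[1]
    chunks = []
    for start in range(0, ref_idx.size, 128):
        sel = points[ref_idx[start : start + 128]]
        # accumulate coordinate-wise to avoid (chunk, n, m) temporaries
        if config.norm == "max":
            d = np.abs(sel[:, 0, None] - points[None, :, 0])
            for c in range(1, m):
                np.maximum(d, np.abs(sel[:, c, None] - points[None, :, c]), out=d)
        else:
            d = (sel[:, 0, None] - points[None, :, 0]) ** 2
            for c in range(1, m):
                d += (sel[:, c, None] - points[None, :, c]) ** 2
            np.sqrt(d, out=d)
        chunks.append(d.ravel())
    return np.concatenate(chunks), int(ref_idx.size)


def _grid_from_distances(dist: np.ndarray, step: float) -> np.ndarray:
    pos = dist[dist > 0]
    if pos.size == 0:
        raise ValueError("all points are identical: no positive pairwise distance")
    lo = float(np.log10(pos.min()))
    hi = float(np.log10(pos.max()))
    n_steps = max(int(np.ceil((hi - lo) / step - 1e-12)), 0)
    grid = lo + step * np.arange(n_steps + 1)
    grid[-1] = max(grid[-1], hi)  # the top of the grid must cover the largest distance
    return grid


def _linear_grid_from_distances(dist: np.ndarray, n_eps: int) -> np.ndarray:
    """log10 of a linear eps grid: n_eps equal increments up to the largest distance."""
    pos = dist[dist > 0]
    if pos.size == 0:
        raise ValueError("all points are identical: no positive pairwise distance")
    dmax = float(pos.max())
    eps = (dmax / n_eps) * np.arange(1, n_eps + 1)
    grid = np.log10(eps)
    grid[-1] = max(grid[-1], float(np.log10(dmax)))
    return grid


def build_eps_grid(points: np.ndarray, config: CorrelationConfig) -> np.ndarray:
    """Increasing log10-radius grid spanning the sampled pairwise distances.

    Runs from log10 of the smallest strictly positive sampled distance to (at
    least) log10 of the largest, in increments of ``config.log_eps_step``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    dist, _ = _ref_distances(points, config)
    return _grid_from_distances(dist, config.log_eps_step)


def correlation_integral(
    points: np.ndarray,
    config: CorrelationConfig,
    log_eps: Optional[np.ndarray] = None,
) -> CorrelationCurve:
    """Estimate the correlation integral of ``points`` over a log-radius grid.

    C(eps) is the average over reference points of the fraction of the other
    points within closed max-norm distance eps.  When ``log_eps`` is not
    given, the grid follows ``config.grid``: linear eps increments up to the
    largest sampled distance (default), or a log10 grid over the sampled
    distances with one extra step prepended below the smallest positive
    distance so that the first rise of the curve is itself visible as a step.
    Leading samples with C < ``config.c_floor`` (and any zero-count samples)
    are dropped.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")

    dist, n_ref = _ref_distances(points, config)
    if log_eps is None:
        if config.grid == "linear":
            grid = _linear_grid_from_distances(dist, config.n_eps)
        else:
            grid = _grid_from_distances(dist, config.log_eps_step)
            grid = np.concatenate([[grid[0] - config.log_eps_step], grid])
    else:
        grid = np.asarray(log_eps, dtype=float)
        if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("log_eps must be a strictly increasing 1-d array")

    with np.errstate(divide="ignore"):
        log_d = np.log10(dist)  # zero distances -> -inf, counted inside every ball

    # counts[k] = number of sampled pairs with log10(d) <= grid[k]; the n_ref
    # zero self-distances are counted inside every ball and removed here.
    which = np.searchsorted(grid, log_d, side="left")
    counts = np.cumsum(np.bincount(np.minimum(which, grid.size), minlength=grid.size + 1))[
        : grid.size
    ].astype(float)
    counts -= n_ref
    total = float(dist.size - n_ref)
    C = counts / total

    keep_from = 0
    floor = max(config.c_floor, np.nextafter(0, 1))
    while keep_from < grid.size - 1 and C[keep_from] < floor:
        keep_from += 1
    grid, C = grid[keep_from:], C[keep_from:]
    if C[0] <= 0:
        raise ValueError("no pairs counted anywhere on the radius grid")

    return CorrelationCurve(log_eps=grid, log_C=np.log10(C), m=points.shape[1], n_points=n)
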