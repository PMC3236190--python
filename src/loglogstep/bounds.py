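"""Analytical bounds on observable step counts in the noiseless case, plus a brute-force oracle.

A noiseless periodic pattern of length p embedded with delay 1 in dimension m
produces p point clusters (one per cyclic shift).  In the maximum norm, the
distance between the clusters at shift k apart is the maximum of m
consecutive componentwise distances d_j(k) = |x_j - x_{j+k}| (indices cyclic).
Grouping the unordered position pairs by shift decomposes the componentwise
distance graph into subgraphs: for k < p/2 a p-cycle of d-values, and, for
even p, one extra shift-p/2 subgraph with p/2 edges whose d-values repeat with
period p/2.

The number of distinct sliding-window maxima of width m over a cyclic
sequence of L generically distinct values lies between ceil(L/m) (attained
when the largest values are spread regularly) and L - m + 1 (attained by a
monotone ordering), collapsing to 1 once m >= L.  Summing over the subgraphs
(distances from different subgraphs are generically distinct) gives the
closed-form step-count bounds:

* odd p:   N_min = (p-1)/2 * ceil(p/m'),          N_max = (p-1)/2 * (p - m' + 1)
* even p:  N_min = (p-2)/2 * ceil(p/m') + ceil(p/(2m)),
           N_max = (p-2)/2 * (p - m' + 1) + max(p/2 - m + 1, 1)

with m' = min(m, p): windows longer than one period add no new comparisons,
so for m > p the values clamp to those at m = p.  At m = 1 both bounds equal
p(p-1)/2 (every comparison yields a winner); at m >= p both equal floor(p/2)
(the shift symmetry d(k) = d(p-k)).

:func:`brute_force_step_count` is the independent numerical check: it builds
the cluster centres explicitly and counts distinct pairwise max-norm
distances under a tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .simulate import Pattern

__all__ = [
    "BoundsResult",
    "SubgraphDecomposition",
    "bounds",
    "brute_force_step_count",
    "decompose",
    "bounds_table",
    "random_pattern",
]


@dataclass(frozen=True)
class BoundsResult:
    """Lower/upper bound on the number of observable steps for (p, m)."""

    n_min: int
    n_max: int
    p: int
    m: int


@dataclass(frozen=True)
class SubgraphDecomposition:
    """Shift-k subgraphs of the componentwise distance graph over p cyclic positions."""

    p: int
    subgraphs: tuple[frozenset[tuple[int, int]], ...]


def _window_max_count_bounds(cycle_len: int, m: int) -> tuple[int, int]:
    """Distinct sliding-window-max count bounds for window m over a cycle of given length."""
    mm = min(m, cycle_len)
    return ceil(cycle_len / mm), cycle_len - mm + 1


def bounds(p: int, m: int) -> BoundsResult:
    """Closed-form lower and maximal numbers of observable steps for (p, m)."""
    if p < 2:
        raise ValueError("pattern length must be >= 2")
    if m < 1:
        raise ValueError("embedding dimension must be >= 1")
    if p % 2 == 1:
        half = (p - 1) // 2
        lo, hi = _window_max_count_bounds(p, m)
        n_min, n_max = half * lo, half * hi
    else:
        cycles = (p - 2) // 2
        lo, hi = _window_max_count_bounds(p, m)
        dlo, dhi = _window_max_count_bounds(p // 2, m)
        n_min, n_max = cycles * lo + dlo, cycles * hi + dhi
    return BoundsResult(n_min=n_min, n_max=n_max, p=p, m=m)


def _cluster_centres(pattern: Pattern, m: int) -> np.ndarray:
    """The p cyclic-shift cluster centres of the noiseless periodic series in dimension m."""
    x = np.asarray(pattern.intervals)
    p = pattern.p
    idx = (np.arange(p)[:, None] + np.arange(m)[None, :]) % p
    return x[idx]


def brute_force_step_count(pattern: Pattern, m: int, tol: float = 1e-9) -> int:
    """Count distinct positive inter-cluster max-norm distances (merged within tolerance).

    ``tol`` is relative to the largest distance.  This realizes, by direct
    enumeration, the number of steps of the ideal noiseless log-log curve.
    """
    if m < 1:
        raise ValueError("embedding dimension must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    centres = _cluster_centres(pattern, m)
    p = centres.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    dists = np.abs(centres[iu] - centres[ju]).max(axis=1)
    top = dists.max()
    if top == 0:
        return 0
    merge = tol * top
    dists = np.sort(dists[dists > merge])
    if dists.size == 0:
        return 0
    return int(1 + np.sum(np.diff(dists) > merge))


def decompose(p: int) -> SubgraphDecomposition:
    """Shift-k edge sets, k = 1..floor(p/2), partitioning all unordered position pairs."""
    if p < 2:
        raise ValueError("pattern length must be >= 2")
    subgraphs = []
    for k in range(1, p // 2 + 1):
        edges = frozenset(tuple(sorted((j, (j + k) % p))) for j in range(p))
        subgraphs.append(edges)
    return SubgraphDecomposition(p=p, subgraphs=tuple(subgraphs))


def bounds_table(p_values: Iterable[int], m_values: Iterable[int]) -> pd.DataFrame:
    """Table of ``n_min/n_max`` entries indexed by embedding dimension m, one column per p."""
    p_values = list(p_values)
    m_values = list(m_values)
    if not p_values or not m_values:
        raise ValueError("p and m ranges must be nonempty")
    data = {}
    for p in p_values:
        col = []
        for m in m_values:
            b = bounds(p, m)
            col.append(f"{b.n_min}/{b.n_max}")
        data[f"p={p}"] = col
    return pd.DataFrame(data, index=pd.Index(m_values, name="m"))


def random_pattern(
    p: int,
    rng: np.random.Generator,
    low: float = 0.5,
    high: float = 2.0,
    min_sep: float = 1e-6,
) -> Pattern:
    """A generic random pattern: i.i.d. uniform intervals, degenerate draws resampled.

    Draws with near-coincident values (pairwise gaps below ``min_sep``) are
    rejected so that the generic-position assumptions of the bounds hold at
    double precision.
    """
    while True:
        x = rng.uniform(low, high, p)
        if np.min(np.diff(np.sort(x))) > min_sep:
            return Pattern(tuple(x))
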