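"""Jitter x noise parameter sweeps: per-cell quality scores, normalization, region labels.

Each grid cell (jitter fraction, noise fraction) is evaluated on ``replicates``
independently seeded synthetic series.  Per replicate the correlation curves
at m = 1, p-1 and p are computed, the three criteria evaluated (criterion (a)
against a small permutation-surrogate ensemble), and the replicate scores
averaged.  Each criterion matrix is then normalized by its grid maximum and
classified into visibility regions: I (excellent), II (fair), III (ambiguous);
criterion (a) uses the two-region variant (II merged into III).

Per-cell seeds are derived from ``numpy.random.SeedSequence((base_seed,
jitter_index, noise_index, replicate_index, stream))`` so any cell is
independently re-runnable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationConfig, EmbeddingConfig, correlation_integral, embed
from .criteria import (
    DEFAULT_PEAK_LEVELS,
    DEFAULT_PLATEAU_LEVELS,
    LevelWeights,
    criterion_a,
    criterion_b,
    criterion_c,
    normalize_over_grid,
)
from .simulate import ISISeries, JitterSpec, NoiseSpec, Pattern, generate_series, make_surrogate

__all__ = ["GridSpec", "PhaseDiagram", "cell_seed", "evaluate_replicate", "sweep", "classify_regions"]

CRITERIA = ("a", "b", "c")


@dataclass(frozen=True)
class GridSpec:
    """Axes of the sweep (fractions in [0, 1]), replicate count and base seed."""

    jitter_values: tuple[float, ...]
    noise_values: tuple[float, ...]
    replicates: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        jv = tuple(float(x) for x in self.jitter_values)
        nv = tuple(float(x) for x in self.noise_values)
        if not jv or not nv:
            raise ValueError("grid axes must be nonempty")
        for vals in (jv, nv):
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError("grid values must lie in [0, 1]")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError("grid values must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "jitter_values", jv)
        object.__setattr__(self, "noise_values", nv)


@dataclass(frozen=True, eq=False)
class PhaseDiagram:
    """Normalized per-criterion score matrices with region labels and provenance."""

    jitter_values: tuple[float, ...]
    noise_values: tuple[float, ...]
    raw: dict  # criterion -> (n_jitter, n_noise) array of replicate-averaged raw scores
    normalized: dict  # criterion -> normalized array (grid maximum = 1)
    regions: dict  # criterion -> array of labels "I" / "II" / "III"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: jitter, noise, criterion, raw/normalized score, region."""
        rows = []
        for crit in CRITERIA:
            for i, j in np.ndindex(self.normalized[crit].shape):
                rows.append(
                    {
                        "jitter": self.jitter_values[i],
                        "noise": self.noise_values[j],
                        "criterion": crit,
                        "raw_score": self.raw[crit][i, j],
                        "normalized_score": self.normalized[crit][i, j],
                        "region": self.regions[crit][i, j],
                    }
                )
        return pd.DataFrame(rows)


def cell_seed(base_seed: int, jitter_index: int, noise_index: int, replicate: int, stream: int = 0) -> int:
    """Deterministic per-cell sub-seed (below 2^31), re-derivable for any single cell."""
    ss = np.random.SeedSequence((base_seed, jitter_index, noise_index, replicate, stream))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _curve(series: ISISeries, m: int, corr: CorrelationConfig, seed: int, n_points: int):
    x = series.intervals[: n_points + (m - 1)]
    pts = embed(x, EmbeddingConfig(m=m))
    return correlation_integral(pts, replace(corr, seed=seed))


def evaluate_replicate(
    pattern: Pattern,
    jitter_fraction: float,
    noise_fraction: float,
    seed_tuple: tuple[int, int, int, int],
    *,
    n_points: int = 10_000,
    corr: CorrelationConfig = CorrelationConfig(),
    jitter_distribution: str = "uniform",
    paradigm: str = "pattern_wise",
    lw_peaks: LevelWeights = DEFAULT_PEAK_LEVELS,
    lw_plateau: LevelWeights = DEFAULT_PLATEAU_LEVELS,
    n_surrogates: int = 5,
    b_dim: int = 1,
) -> tuple[float, float, float]:
    """Scores (q_a, q_b, q_c) for one replicate of one grid cell."""
    base, ji, ni, rep = seed_tuple
    p = pattern.p
    m_max = max(p, b_dim)
    series = generate_series(
        pattern,
        JitterSpec(fraction=jitter_fraction, distribution=jitter_distribution),
        NoiseSpec(fraction=noise_fraction, paradigm=paradigm),
        n_events=n_points + (m_max - 1),
        seed=cell_seed(base, ji, ni, rep, stream=0),
    )
    curve_b = _curve(series, b_dim, corr, cell_seed(base, ji, ni, rep, 1), n_points)
    curve_lo = _curve(series, p - 1, corr, cell_seed(base, ji, ni, rep, 2), n_points)
    curve_hi = _curve(series, p, corr, cell_seed(base, ji, ni, rep, 3), n_points)
    surr_curves = []
    for s in range(n_surrogates):
        surr = make_surrogate(series, cell_seed(base, ji, ni, rep, 10 + 2 * s))
        surr_curves.append(_curve(surr, p, corr, cell_seed(base, ji, ni, rep, 11 + 2 * s), n_points))
    q_a = criterion_a(curve_hi, surr_curves, lw_peaks)
    q_b = criterion_b(curve_b, p, lw_peaks)
    q_c = criterion_c(curve_hi, curve_lo, lw_plateau)
    return q_a, q_b, q_c


def sweep(
    pattern: Pattern,
    grid: GridSpec,
    *,
    n_points: int = 10_000,
    corr: CorrelationConfig = CorrelationConfig(),
    paradigm: str = "pattern_wise",
    lw_peaks: LevelWeights = DEFAULT_PEAK_LEVELS,
    lw_plateau: LevelWeights = DEFAULT_PLATEAU_LEVELS,
    n_surrogates: int = 5,
    thresholds: tuple[float, float] = (0.66, 0.33),
    average: str = "mean",
) -> PhaseDiagram:
    """Evaluate all three criteria over the jitter x noise grid.

    Replicates are averaged (``mean`` by default, ``median`` as a robust
    option); each criterion matrix is normalized by its grid maximum.  Cells
    where curve construction fails are flagged in the metadata and carry NaN
    scores rather than being silently dropped.
    """
    if average not in ("mean", "median"):
        raise ValueError("average must be 'mean' or 'median'")
    reduce = np.mean if average == "mean" else np.median
    shape = (len(grid.jitter_values), len(grid.noise_values))
    raw = {c: np.full(shape, np.nan) for c in CRITERIA}
    failed: list[dict] = []
    for i, jf in enumerate(grid.jitter_values):
        for j, nf in enumerate(grid.noise_values):
            scores = []
            for r in range(grid.replicates):
                try:
                    scores.append(
                        evaluate_replicate(
                            pattern, jf, nf, (grid.base_seed, i, j, r),
                            n_points=n_points, corr=corr, paradigm=paradigm,
                            lw_peaks=lw_peaks, lw_plateau=lw_plateau,
                            n_surrogates=n_surrogates,
                        )
                    )
                except ValueError as err:
                    failed.append({"jitter": jf, "noise": nf, "replicate": r, "error": str(err)})
            if scores:
                arr = np.asarray(scores)
                for k, c in enumerate(CRITERIA):
                    raw[c][i, j] = reduce(arr[:, k])
    normalized, regions, unnormalizable = {}, {}, []
    for c in CRITERIA:
        try:
            normalized[c] = normalize_over_grid(raw[c])
        except ValueError:
            # no cell with a positive score: flag instead of failing the sweep
            unnormalizable.append(c)
            normalized[c] = np.full(shape, np.nan)
        regions[c] = classify_regions(normalized[c], thresholds, two_region=(c == "a"))
    metadata = {
        "pattern": pattern.intervals,
        "n_points": n_points,
        "n_ref": corr.n_ref,
        "grid": corr.grid,
        "n_eps": corr.n_eps,
        "log_eps_step": corr.log_eps_step,
        "c_floor": corr.c_floor,
        "paradigm": paradigm,
        "replicates": grid.replicates,
        "base_seed": grid.base_seed,
        "peak_levels": lw_peaks.levels,
        "peak_weights": lw_peaks.weights,
        "plateau_levels": lw_plateau.levels,
        "plateau_weights": lw_plateau.weights,
        "n_surrogates": n_surrogates,
        "thresholds": thresholds,
        "average": average,
        "failed_cells": failed,
        "unnormalizable_criteria": unnormalizable,
    }
    return PhaseDiagram(
        jitter_values=grid.jitter_values,
        noise_values=grid.noise_values,
        raw=raw,
        normalized=normalized,
        regions=regions,
        metadata=metadata,
    )


def classify_regions(
    normalized_matrix: np.ndarray,
    thresholds: tuple[float, float] = (0.66, 0.33),
    two_region: bool = False,
) -> np.ndarray:
    """Map normalized scores to visibility regions.

    score >= t_hi -> "I" (excellent); t_lo <= score < t_hi -> "II" (fair);
    score < t_lo -> "III" (ambiguous).  In ``two_region`` mode II is merged
    into III.  NaN cells (failed) are labelled "III".
    """
    t_hi, t_lo = thresholds
    if not (0.0 < t_lo < t_hi < 1.0):
        raise ValueError("thresholds must satisfy 0 < t_lo < t_hi < 1")
    arr = np.asarray(normalized_matrix, dtype=float)
    labels = np.full(arr.shape, "III", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[arr >= t_lo] = "III" if two_region else "II"
        labels[arr >= t_hi] = "I"
    return labels
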