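"""Practical screening of a series for candidate pattern lengths.

Embeds a series at m = 1..p_max, computes all correlation curves, and scores
each candidate pattern length p by the plateau-flatness difference between
the consecutive dimensions (p, p-1) — criterion (c) — measured against the
same quantity on a permutation surrogate.  Criteria (a) and (b) at their
indicated dimensions, and the analytical step-count bounds table, are
reported for context.

A candidate counts as *supported* when its margin over the surrogate is both
positive and a substantial fraction (half) of the best margin seen; the
recommended pattern length is the **largest** supported candidate, because
embedding windows longer than the true period add no new componentwise
comparisons, so the plateau difference collapses for every p beyond the
actual pattern length while remaining large up to it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .bounds import bounds_table
from .correlation import CorrelationConfig, EmbeddingConfig, correlation_integral, embed
from .criteria import (
    DEFAULT_PEAK_LEVELS,
    DEFAULT_PLATEAU_LEVELS,
    LevelWeights,
    criterion_a,
    criterion_b,
    criterion_c,
)
from .simulate import ISISeries, make_surrogate

__all__ = ["CandidateScore", "GuidelineReport", "run_guideline"]


@dataclass(frozen=True)
class CandidateScore:
    """Evidence for one candidate pattern length."""

    p: int
    c_score: float  # plateau difference, dimensions (p, p-1)
    c_surrogate: float  # same on the permutation surrogate
    q_a: float  # single-step criterion at m = p
    q_b: float  # exactly-p-peaks criterion at m = 1
    supported: bool = False

    @property
    def margin(self) -> float:
        return self.c_score - self.c_surrogate


@dataclass(frozen=True, eq=False)
class GuidelineReport:
    candidates: tuple[CandidateScore, ...]  # sorted, strongest first
    p_max: int
    diagnostics: tuple[str, ...] = ()
    bounds: Optional[object] = None  # DataFrame of n_min/n_max per (m, p)

    @property
    def top_candidate(self) -> Optional[int]:
        supported = [c.p for c in self.candidates if c.supported]
        return max(supported) if supported else None

    def render_text(self) -> str:
        lines = ["candidate pattern lengths (strongest first):"]
        lines.append("  p   plateau-diff   surrogate   q_a     q_b     supported")
        for c in self.candidates:
            lines.append(
                f"  {c.p:<3d} {c.c_score:>12.3f} {c.c_surrogate:>11.3f}"
                f" {c.q_a:>7.3f} {c.q_b:>7.3f}   {'yes' if c.supported else 'no'}"
            )
        for msg in self.diagnostics:
            lines.append(f"note: {msg}")
        if self.bounds is not None:
            lines.append("")
            lines.append("ideal-case step-count bounds (n_min/n_max):")
            lines.append(self.bounds.to_string())
        return "\n".join(lines)


def run_guideline(
    series: ISISeries,
    p_max: int,
    corr: CorrelationConfig = CorrelationConfig(),
    lw_peaks: LevelWeights = DEFAULT_PEAK_LEVELS,
    lw_plateau: LevelWeights = DEFAULT_PLATEAU_LEVELS,
    n_surrogates: int = 5,
    seed: int = 0,
) -> GuidelineReport:
    """Screen ``series`` for periodic patterns of length 2..p_max.

    Degenerate input (for instance a constant series, which has no positive
    pairwise distance) yields a diagnostic report instead of an exception.
    """
    if p_max < 2:
        raise ValueError("p_max must be >= 2")
    if len(series) <= p_max:
        raise ValueError("series shorter than the largest requested embedding")
    ss = np.random.SeedSequence((seed, 0))
    sub = ss.generate_state(2 * p_max + 2 + n_surrogates, np.uint32) % (2**31)

    surrogate = make_surrogate(series, int(sub[0]))

    def curve_at(data: ISISeries, m: int, s: int):
        cfg = replace(corr, seed=s)
        return correlation_integral(embed(data, EmbeddingConfig(m=m)), cfg)

    curves, surr_curves = {}, {}
    for m in range(1, p_max + 1):
        try:
            curves[m] = curve_at(series, m, int(sub[2 * m]))
            surr_curves[m] = curve_at(surrogate, m, int(sub[2 * m + 1]))
        except ValueError as err:
            return GuidelineReport(
                candidates=(),
                p_max=p_max,
                diagnostics=(f"degenerate input at m={m}: {err}",),
            )

    candidates = []
    diagnostics: list[str] = []
    for p in range(2, p_max + 1):
        try:
            c_score = criterion_c(curves[p], curves[p - 1], lw_plateau)
            c_surr = criterion_c(surr_curves[p], surr_curves[p - 1], lw_plateau)
        except ValueError as err:
            diagnostics.append(f"p={p}: {err}")
            continue
        extra = [
            curve_at(make_surrogate(series, int(sub[2 * p_max + 2 + s])), p, int(sub[1]) + s)
            for s in range(max(n_surrogates - 1, 0))
        ]
        q_a = criterion_a(curves[p], [surr_curves[p], *extra], lw_peaks)
        q_b = criterion_b(curves[1], p, lw_peaks)
        candidates.append(CandidateScore(p=p, c_score=c_score, c_surrogate=c_surr, q_a=q_a, q_b=q_b))

    best_margin = max((c.margin for c in candidates), default=0.0)
    if best_margin > 0:
        candidates = [
            replace(c, supported=c.margin > 0.5 * best_margin) for c in candidates
        ]
    candidates.sort(key=lambda c: c.margin, reverse=True)
    table = bounds_table(range(2, p_max + 1), range(1, p_max + 1))
    return GuidelineReport(
        candidates=tuple(candidates),
        p_max=p_max,
        diagnostics=tuple(diagnostics),
        bounds=table,
    )
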