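"""Synthetic interspike-interval (ISI) series: periodic patterns under jitter and insertion noise.

A regular signal is a cyclic repetition of a short pattern of intervals.  Two
contaminations are modelled:

* **jitter** — an additive perturbation of every pattern interval, scaled as a
  fraction of the *smallest* pattern interval (uniform by default; Gaussian and
  a truncated long-tailed alternative are available, the differences being
  negligible in the regime of interest);
* **insertion noise** — a nominal fraction of all events drawn from a random
  interval distribution instead of the pattern.  Noise can replace single
  events (``event_wise``) or compete with the insertion of whole patterns
  (``pattern_wise``): with probability ``q_tilde`` the next ``p`` events are a
  full (jittered) pattern, otherwise a single noise interval is emitted.  For
  the nominal per-event noise fraction ``f`` to be comparable across the two
  paradigms the insertion probability must be rescaled, see
  :func:`rescale_pattern_probability`.

Permutation surrogates (:func:`make_surrogate`) destroy the sequential order
while preserving the interval value distribution exactly; they provide the
null against which step structure is judged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "JitterSpec",
    "NoiseSpec",
    "ISISeries",
    "generate_series",
    "apply_jitter",
    "rescale_pattern_probability",
    "make_surrogate",
]

#: Pattern used throughout the worked examples: period three, intervals 1, 3, 4.
DEFAULT_PATTERN_INTERVALS = (1.0, 3.0, 4.0)


@dataclass(frozen=True)
class Pattern:
    """One period of the regular signal: an ordered tuple of positive intervals."""

    intervals: tuple[float, ...]

    def __post_init__(self) -> None:
        iv = tuple(float(x) for x in self.intervals)
        if len(iv) < 2:
            raise ValueError("a pattern needs at least two intervals")
        if any(x <= 0 for x in iv):
            raise ValueError("pattern intervals must be strictly positive")
        object.__setattr__(self, "intervals", iv)

    @property
    def p(self) -> int:
        """Pattern length (number of intervals per period)."""
        return len(self.intervals)

    @property
    def min_interval(self) -> float:
        return min(self.intervals)

    @property
    def max_interval(self) -> float:
        return max(self.intervals)

    @classmethod
    def from_string(cls, text: str) -> "Pattern":
        """Parse a comma-separated pattern such as ``"1,3,4"``."""
        return cls(tuple(float(t) for t in text.replace(";", ",").split(",") if t.strip()))


@dataclass(frozen=True)
class JitterSpec:
    """Additive perturbation of pattern intervals.

    ``fraction`` scales the perturbation relative to the smallest pattern
    interval: for the uniform distribution it is the half-width (signed) or
    width (unsigned), for the Gaussian the standard deviation, and for the
    long-tailed option the Cauchy scale.
    """

    fraction: float = 0.0
    distribution: str = "uniform"  # uniform | gaussian | long_tailed
    signed: bool = True

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("jitter fraction must be >= 0")
        if self.distribution not in ("uniform", "gaussian", "long_tailed"):
            raise ValueError(f"unknown jitter distribution {self.distribution!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Insertion noise: nominal per-event fraction, paradigm, and interval law.

    The noise interval distribution is uniform on ``(low, high]``; by default
    ``high = 1.5 * max(pattern)`` (resolved at generation time), spanning and
    exceeding the pattern's own scale without introducing a new free scale.
    """

    fraction: float = 0.0
    paradigm: str = "pattern_wise"  # pattern_wise | event_wise
    low: float = 0.0
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("noise fraction must lie in [0, 1]")
        if self.paradigm not in ("pattern_wise", "event_wise"):
            raise ValueError(f"unknown noise paradigm {self.paradigm!r}")
        if self.low < 0:
            raise ValueError("noise interval lower bound must be >= 0")
        if self.high is not None and self.high <= self.low:
            raise ValueError("noise interval upper bound must exceed the lower bound")


@dataclass(frozen=True, eq=False)
class ISISeries:
    """A finite sequence of positive intervals, optionally with provenance labels."""

    intervals: np.ndarray
    labels: Optional[np.ndarray] = None  # per-event, "pattern" or "noise"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1 or iv.size == 0:
            raise ValueError("an ISI series must be a nonempty 1-d sequence")
        if np.any(iv <= 0):
            raise ValueError("all intervals must be strictly positive")
        object.__setattr__(self, "intervals", iv)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != iv.shape:
                raise ValueError("labels must match intervals in length")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def noise_fraction(self) -> Optional[float]:
        """Empirical fraction of noise-labelled events, if labels are present."""
        if self.labels is None:
            return None
        return float(np.mean(self.labels == "noise"))


def rescale_pattern_probability(noise_fraction: float, p: int) -> float:
    """Pattern-insertion probability q_tilde for the pattern-wise paradigm.

    Each Bernoulli draw emits either a whole pattern (``p`` events, probability
    ``q_tilde``) or one noise event.  The expected per-event noise fraction is
    ``(1 - q_tilde) / ((1 - q_tilde) + q_tilde * p)``; solving this for
    ``q_tilde`` at the nominal ``noise_fraction`` gives

        q_tilde = (1 - f) / (1 - f + f * p).
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise fraction must lie in [0, 1]")
    if p < 2:
        raise ValueError("pattern length must be >= 2")
    f = float(noise_fraction)
    return (1.0 - f) / ((1.0 - f) + f * p)


def _draw_jitter(rng: np.random.Generator, spec: JitterSpec, scale: float, size: int) -> np.ndarray:
    if spec.distribution == "uniform":
        if spec.signed:
            return rng.uniform(-scale, scale, size)
        return rng.uniform(0.0, scale, size)
    if spec.distribution == "gaussian":
        d = rng.normal(0.0, scale, size)
        return d if spec.signed else np.abs(d)
    # long-tailed: location-zero Cauchy; positivity is restored by resampling
    d = scale * rng.standard_cauchy(size)
    return d if spec.signed else np.abs(d)


def _jitter_values(
    values: np.ndarray, spec: JitterSpec, rng: np.random.Generator, reference: float
) -> np.ndarray:
    """Jitter ``values`` in place of the pattern; resample any non-positive result."""
    if spec.fraction == 0.0:
        return values.copy()
    scale = spec.fraction * reference
    out = values + _draw_jitter(rng, spec, scale, values.size)
    # Resampling (rather than clipping) preserves the shape of the jitter law.
    bad = out <= 0
    while np.any(bad):
        out[bad] = values[bad] + _draw_jitter(rng, spec, scale, int(bad.sum()))
        bad = out <= 0
    return out


def apply_jitter(
    intervals: Sequence[float],
    jitter: JitterSpec,
    seed: int,
    reference: Optional[float] = None,
) -> np.ndarray:
    """Return ``intervals`` perturbed by ``jitter``.

    The perturbation scale is ``jitter.fraction`` times ``reference`` (the
    smallest of ``intervals`` when not given).  Outputs are strictly positive:
    non-positive draws are resampled.
    """
    values = np.asarray(intervals, dtype=float)
    if values.size == 0:
        raise ValueError("empty interval sequence")
    ref = float(np.min(values)) if reference is None else float(reference)
    rng = np.random.default_rng(seed)
    return _jitter_values(values, jitter, rng, ref)


def _noise_high(pattern: Pattern, noise: NoiseSpec) -> float:
    return 1.5 * pattern.max_interval if noise.high is None else noise.high


def _draw_noise(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    out = rng.uniform(low, high, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.uniform(low, high, int(bad.sum()))
        bad = out <= 0
    return out


def generate_series(
    pattern: Pattern,
    jitter: JitterSpec,
    noise: NoiseSpec,
    n_events: int,
    seed: int,
) -> ISISeries:
    """Generate a contaminated patterned ISI series of at least ``n_events`` intervals.

    ``pattern_wise``: repeated Bernoulli draws; with the rescaled probability
    ``q_tilde`` a whole jittered pattern (``p`` events) is appended, otherwise
    one noise interval.  Generation stops at the first draw reaching
    ``n_events``; trailing excess (at most ``p - 1`` events) is retained.

    ``event_wise``: each event is independently a pattern event with
    probability ``1 - fraction`` (the pattern pointer advances only when a
    pattern event is emitted) or a noise interval otherwise.

    Labels record per-event provenance.  Identical seeds yield identical output.
    """
    if n_events < pattern.p:
        raise ValueError("n_events must be at least the pattern length")
    rng = np.random.default_rng(seed)
    p = pattern.p
    base = np.asarray(pattern.intervals, dtype=float)
    ref = pattern.min_interval
    low, high = noise.low, _noise_high(pattern, noise)

    intervals: list[float] = []
    labels: list[str] = []

    if noise.paradigm == "pattern_wise":
        q_tilde = rescale_pattern_probability(noise.fraction, p)
        while len(intervals) < n_events:
            if rng.random() < q_tilde:
                jittered = _jitter_values(base, jitter, rng, ref)
                intervals.extend(jittered.tolist())
                labels.extend(["pattern"] * p)
            else:
                intervals.append(float(_draw_noise(rng, low, high, 1)[0]))
                labels.append("noise")
    else:  # event_wise
        phase = 0
        while len(intervals) < n_events:
            if rng.random() < 1.0 - noise.fraction:
                value = _jitter_values(base[phase : phase + 1], jitter, rng, ref)[0]
                intervals.append(float(value))
                labels.append("pattern")
                phase = (phase + 1) % p
            else:
                intervals.append(float(_draw_noise(rng, low, high, 1)[0]))
                labels.append("noise")

    return ISISeries(np.asarray(intervals), np.asarray(labels), seed=seed)


def make_surrogate(series: ISISeries, seed: int) -> ISISeries:
    """Uniformly random permutation of the series; the value multiset is preserved."""
    if len(series) == 0:
        raise ValueError("cannot permute an empty series")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(series))
    labels = None if series.labels is None else series.labels[perm]
    return ISISeries(series.intervals[perm], labels, seed=seed)
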