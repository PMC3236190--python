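import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import loglogstep as ls

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pattern134() -> ls.Pattern:
    return ls.Pattern((1.0, 3.0, 4.0))


@pytest.fixture(scope="session")
def noiseless_series(pattern134) -> ls.ISISeries:
    """Exact periodic repetition of (1, 3, 4): zero jitter, zero noise."""
    return ls.generate_series(
        pattern134, ls.JitterSpec(0.0), ls.NoiseSpec(0.0), n_events=600, seed=11
    )


@pytest.fixture(scope="session")
def all_refs_config() -> ls.CorrelationConfig:
    """Full pairwise computation: every point is a reference point."""
    return ls.CorrelationConfig(n_ref=10**9, seed=0)


def curve_of(series, m, config, n_points=None):
    x = series.intervals if n_points is None else series.intervals[: n_points + (m - 1)]
    pts = ls.embed(x, ls.EmbeddingConfig(m=m))
    return ls.correlation_integral(pts, config)
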