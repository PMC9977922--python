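import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dorsalstream import build_default_model
from dorsalstream.simulate import SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: all six long projections at the coupled-network default strength
ALL_K10 = {k: 10.0 for k in ("k12", "k15", "k25", "k21", "k51", "k52")}
ALL_K0 = {k: 0.0 for k in ("k12", "k15", "k25", "k21", "k51", "k52")}


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def short_cfg():
    """Cheap configuration for functional (non-spectral) checks."""
    return SimulationConfig(duration=40.0, transient=10.0, seed=7)


@pytest.fixture(scope="session")
def reduced_cfg():
    """Reduced-scale analysis protocol: 150 s runs, 30 s transient."""
    return SimulationConfig(duration=150.0, transient=30.0)


def coupled_overrides(**kw):
    ov = dict(ALL_K10)
    ov.update({k: float(v) for k, v in kw.items()})
    return ov
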