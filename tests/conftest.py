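import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import inhibkin as ik

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def mm():
    """Michaelis-Menten parameters in the assay's working range."""
    return ik.MMParameters(Km=1.5, Vmax=1.0)


@pytest.fixture
def mixed_inhib():
    """Sub-micromolar mixed inhibitor with single-figure cooperativity."""
    return ik.InhibitionParameters(Ki=0.8, alpha=3.2)


@pytest.fixture
def competitive_inhib():
    return ik.InhibitionParameters(Ki=0.8, mode="competitive")


@pytest.fixture
def noiseless_mixed_table(mm, mixed_inhib):
    """Exact mixed-model velocities on the default 8 x 4 design."""
    cfg = ik.SimulationConfig(seed=0, mm=mm, inhib=mixed_inhib, noise_cv=0.0)
    return ik.simulate_velocity_table(cfg)


@pytest.fixture
def noisy_mixed_table(mm, mixed_inhib):
    cfg = ik.SimulationConfig(seed=42, mm=mm, inhib=mixed_inhib, noise_cv=0.05)
    return ik.simulate_velocity_table(cfg)


@pytest.fixture
def potency_613():
    """Potency of the most-studied inhibitor: pIC50 6.13, unit Hill slope."""
    return ik.PotencyParameters(pIC50=6.13, hill_slope=1.0)


@pytest.fixture
def log_conc_grid():
    """8 log-spaced inhibitor levels spanning the transition around 0.74 uM."""
    return tuple(np.geomspace(0.0074, 74.0, 8))
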