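import numpy as np
import pytest
from hypothesis import settings

from fiberfv.hill import HillParameters, velocity_at_force
from fiberfv.synthetic import (
    NoiseSpec,
    PopulationSpec,
    StudyConfig,
    default_population_spec,
    make_study,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("ci")


def noiseless_points(params: HillParameters, n: int = 16):
    """Exact (force, velocity) samples spanning the Hill curve."""
    forces = np.linspace(0.03, 0.85, n) * params.po
    velocities = np.array([velocity_at_force(params, f) for f in forces])
    return forces, velocities


@pytest.fixture(scope="session")
def default_spec():
    return default_population_spec()


@pytest.fixture(scope="session")
def clean_small_study():
    """Zero-noise, zero-rundown, zero-drift study: 5 fibers per group."""
    from dataclasses import replace

    spec = default_population_spec()
    spec = replace(
        spec,
        groups=tuple(replace(g, n=5) for g in spec.groups),
        rundown_mean=0.0,
        rundown_sd=0.0,
        sl_drift_sd=0.0,
    )
    return make_study(StudyConfig(spec, noise=NoiseSpec.zero()), seed=20240915)


@pytest.fixture(scope="session")
def default_study():
    """One full default-noise emulation study (85 + 49 fibers)."""
    return make_study(StudyConfig(default_population_spec()), seed=0)
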