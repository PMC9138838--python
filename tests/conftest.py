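import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from memshadow.synthetic_membrane import (
    MembraneSpec,
    build_membrane,
    equal_abundance_composition,
)


@pytest.fixture(autouse=True)
def _quiet_midplane_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_membrane():
    """Small equal-abundance membrane with strong planted co-localization."""
    spec = MembraneSpec(
        box=(20.0, 20.0, 10.0),
        composition=equal_abundance_composition(count=280),
        np_count=100,
        np_colocal_strength=0.9,
        seed=42,
    )
    traj, truth = build_membrane(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def flat_membrane():
    """Flat bilayer (no undulations): exact planted geometry."""
    spec = MembraneSpec(
        box=(20.0, 20.0, 10.0),
        composition=equal_abundance_composition(count=280),
        np_count=50,
        undulation_amplitude=0.0,
        seed=7,
    )
    traj, truth = build_membrane(spec)
    return spec, traj, truth
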