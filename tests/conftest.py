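import numpy as np
import pytest

from sorpflex.builder import make_bulk_water
from sorpflex.energy import NonbondedSettings
from sorpflex.md import IntegratorSpec, MDEngine


@pytest.fixture(scope="session")
def small_water_equil():
    """64 SPC/E waters, briefly equilibrated at 300 K (shared by analysis
    unit tests that need a liquid-like configuration, not by acceptance
    checks, which run their own longer protocol)."""
    state = make_bulk_water(n=64, density=0.997, seed=7)
    settings = NonbondedSettings(cutoff=0.6)
    eng = MDEngine(state,
                   IntegratorSpec(T_target=300.0, ensemble="NVT",
                                  thermostat="langevin", langevin_gamma=10.0),
                   settings=settings, rng=np.random.default_rng(17))
    eng.initialize_velocities(300.0)
    eng.run(3000)
    frames = []
    for _ in range(5):
        eng.run(400)
        frames.append(state.copy())
    return {"state": state, "frames": frames, "settings": settings,
            "n_water": 64}


@pytest.fixture
def rng():
    return np.random.default_rng(123)
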