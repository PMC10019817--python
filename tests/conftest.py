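import numpy as np
import pytest

from gatedose import dose, motion


@pytest.fixture(scope="session")
def phantom():
    return dose.Phantom()


@pytest.fixture(scope="session")
def toy_plan(phantom):
    return dose.make_toy_plan(phantom, seed=0)


@pytest.fixture(scope="session")
def planned_dose(toy_plan, phantom):
    return dose.compute_dose(toy_plan, phantom)


@pytest.fixture()
def regular_breathing():
    """Regular breathing: 4 s period, 10 mm CC amplitude, no jitter,
    drift or noise — the reference trace for gating checks."""
    return motion.BreathingParams(
        period_s=4.0,
        period_sd=0.0,
        amp_mm=(2.0, 10.0, 5.0),
        amp_sd_frac=0.0,
        drift_mm_per_min=(0.0, 0.0, 0.0),
        noise_sd_mm=0.0,
        seed=1,
    )


@pytest.fixture()
def jittered_breathing():
    return motion.BreathingParams(seed=42)


def rpm_of(params, duration_s=300.0):
    return motion.generate_external_trace(params, duration_s)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
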