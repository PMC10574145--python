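import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chitinmech import (
    SyntheticCurveSpec,
    TwoStateParameters,
    generate_fec,
    normalize_curve,
    segment_curve,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params() -> TwoStateParameters:
    return TwoStateParameters()


@pytest.fixture(scope="session")
def noiseless_norms(base_params):
    """Factory: normalized noiseless ensembles keyed by (ΔG, seed), cached."""
    cache = {}

    def make(bridge_energy: float, seed: int, n_curves: int = 5, n_units: int = 50):
        key = (bridge_energy, seed, n_curves, n_units)
        if key not in cache:
            spec = SyntheticCurveSpec(
                params=base_params.replace(bridge_energy=bridge_energy),
                force_noise=0.0,
                n_curves=n_curves,
                n_units=n_units,
                seed=seed,
            )
            curves = generate_fec(spec)
            cache[key] = [normalize_curve(c, segment_curve(c)) for c in curves]
        return cache[key]

    return make


@pytest.fixture(scope="session")
def noisy_norms(base_params):
    """20 normalized curves at ΔG = 5.53 k_BT with σ = 10 pN force noise."""
    spec = SyntheticCurveSpec(
        params=base_params.replace(bridge_energy=5.53),
        force_noise=10.0,
        n_curves=20,
        seed=7,
    )
    curves = generate_fec(spec)
    return [normalize_curve(c, segment_curve(c)) for c in curves]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
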