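import numpy as np
import pytest

from phagedyn import (
    BurstProfile,
    KineticParameters,
    build_distribution,
    normalize_beta_max,
)


@pytest.fixture
def params() -> KineticParameters:
    """A mid-range, well-behaved kinetic parameter set."""
    return KineticParameters(
        r_max=1.0,
        K_C=1e9,
        phi_max=1e-8,
        P_50=1e8,
        delta_U=0.1,
        delta_I=0.1,
        delta_P=0.1,
        beta_0_mean=100.0,
        r_beta=2.0,
        D=0.2,
        beta_tau50=0.8,
        U_init=1e5,
        P_init=1e6,
    )


@pytest.fixture
def lognormal_dist():
    return build_distribution("lognormal", 1.0, 0.3, 0.0)


@pytest.fixture
def lognormal_burst(params, lognormal_dist) -> BurstProfile:
    bmax = normalize_beta_max(
        params.beta_0_mean, lognormal_dist, params.r_beta, params.D,
        params.beta_tau50,
    )
    return BurstProfile("latent-dependent", params.beta_0_mean, bmax)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(120659)
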