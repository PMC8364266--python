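"""Shared fixtures: phantom specs and cohorts at desk-test scale."""

import numpy as np
import pytest

from mrsct.phantom import PhantomSpec, generate_cohort, generate_phantom


def zero_noise(spec: PhantomSpec) -> PhantomSpec:
    """Copy of a spec with all stochastic image effects disabled."""
    import dataclasses

    return dataclasses.replace(
        spec,
        noise_sd=0.0,
        bias_amplitude=0.0,
        ct_stats={t: (m, 0.0) for t, (m, _) in spec.ct_stats.items()},
        mri_stats={t: (m, 0.0) for t, (m, _) in spec.mri_stats.items()},
    )


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Half-scale geometry on a (4, 48, 48) grid: fast training tests."""
    return PhantomSpec(seed=7).scaled((4, 48, 48), 0.5)


@pytest.fixture(scope="session")
def zero_noise_spec(default_spec) -> PhantomSpec:
    return zero_noise(default_spec)


@pytest.fixture(scope="session")
def zero_noise_phantom(zero_noise_spec):
    return generate_phantom(zero_noise_spec, 0)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return generate_phantom(default_spec, 0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec, 6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
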