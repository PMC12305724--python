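"""Shared fixtures: small seeded synthetic cohorts and spectra."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from carotchem.synthetic import (
    ScatterNoiseModel,
    default_groups,
    generate_metabolite_profiles,
    purple_groups,
    simulate_pure_spectra,
    simulate_spectra,
)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def scaled_purple_groups(fraction: float = 0.25):
    """Purple groups with sizes scaled down (minimum 3 samples each)."""
    return [
        replace(g, n_samples=max(3, round(g.n_samples * fraction)))
        for g in purple_groups()
    ]


@pytest.fixture(scope="session")
def small_purple_profiles():
    """~42-sample purple cohort, fixed seed."""
    return generate_metabolite_profiles(scaled_purple_groups(0.25), seed=11)


@pytest.fixture(scope="session")
def small_full_profiles():
    """Scaled-down seven-group cohort including non-purple samples."""
    groups = [replace(g, n_samples=max(3, g.n_samples // 6)) for g in default_groups()]
    return generate_metabolite_profiles(groups, seed=12)


@pytest.fixture(scope="session")
def pure_components():
    return simulate_pure_spectra()


@pytest.fixture(scope="session")
def noiseless_spectra(small_purple_profiles, pure_components):
    """Exact Beer-Lambert spectra (no scatter, no noise, single replicate)."""
    return simulate_spectra(
        small_purple_profiles, pure=pure_components,
        scatter=ScatterNoiseModel.off(), replicates=1, seed=13,
    )


@pytest.fixture(scope="session")
def noisy_spectra(small_purple_profiles, pure_components):
    """Default-noise triplicate spectra for the small purple cohort."""
    return simulate_spectra(
        small_purple_profiles, pure=pure_components, replicates=3, seed=14
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
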