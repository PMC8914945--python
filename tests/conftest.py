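"""Shared fixtures: component library, grids, and generated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from lsratio import (
    GeneratorConfig,
    PreprocessConfig,
    default_library,
    generate_dataset,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def full_grid():
    """The raw generation grid, 600-4000 cm^-1 at 2 cm^-1."""
    return GeneratorConfig().wavenumbers()


@pytest.fixture(scope="session")
def default_dataset():
    """One full default campaign (259 spectra, seed 0); shared read-only."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def small_config():
    """A fast campaign: 4 sessions of 10 measurements, short replicate runs."""
    return GeneratorConfig(
        n_sessions=4,
        session_group_sizes=(10, 10, 10, 10),
        replicates_per_sample=(2, 4),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def clean_config():
    """Noise- and artifact-free configuration (exact Beer-Lambert data)."""
    return GeneratorConfig(
        n_sessions=4,
        session_group_sizes=(10, 10, 10, 10),
        replicates_per_sample=(2, 4),
        noise_sd=0.0,
        session_gain_sd=0.0,
        dcm_vapor_max=0.0,
        water_vapor_max=0.0,
        water_vapor_fraction=0.0,
        baseline_offset_sd=0.0,
        baseline_slope_sd=0.0,
        baseline_drift_sd=0.0,
        baseline_texture_sd=0.0,
        peak_jitter_sd=0.0,
        seed=5,
    )


@pytest.fixture
def clean_preprocess():
    """Preprocessing with noiseless zap fill (for exact-recovery tests)."""
    return PreprocessConfig(zap_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
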