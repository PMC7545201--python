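import numpy as np
import pytest

from nmropls.pipeline import RunConfig, process_cohort
from nmropls.simulate import (
    default_brain_design,
    default_plasma_design,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def plasma_cohort():
    design = default_plasma_design(seed=7)
    spectra, metadata, truth = simulate_cohort(design)
    return design, spectra, metadata, truth


@pytest.fixture(scope="session")
def plasma_matrix(plasma_cohort):
    _, spectra, metadata, _ = plasma_cohort
    return process_cohort(spectra, list(metadata.group), RunConfig(matrix="plasma"))


@pytest.fixture(scope="session")
def brain_cohort():
    design = default_brain_design("strong", seed=2)
    spectra, metadata, truth = simulate_cohort(design)
    return design, spectra, metadata, truth


@pytest.fixture(scope="session")
def brain_matrix(brain_cohort):
    _, spectra, metadata, _ = brain_cohort
    return process_cohort(spectra, list(metadata.group), RunConfig(matrix="brain"))


@pytest.fixture(scope="session")
def separated_cohort():
    """Strongly separated plasma cohort (low noise, doubled effects)."""
    base = default_plasma_design(seed=7)
    design = default_plasma_design(
        seed=7,
        noise_sd=0.02,
        biological_sd=0.03,
        effects={k: 2 * v for k, v in base.effects.items()},
    )
    spectra, metadata, _ = simulate_cohort(design)
    return design, spectra, metadata


@pytest.fixture(scope="session")
def separated_matrix(separated_cohort):
    _, spectra, metadata = separated_cohort
    return process_cohort(spectra, list(metadata.group), RunConfig(matrix="plasma"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
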