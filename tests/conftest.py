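import numpy as np
import pytest

from qpatsim import (
    ExperimentConfig,
    PhantomSpec,
    build_phantom,
    run_experiment,
)

# Desk-scale problem sizes: the full-pitch phantom for geometry checks and
# a reduced-photon pipeline run shared by the end-to-end tests.
N_PHOTONS_PIPELINE = 400_000


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_grid(default_spec):
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic experiment: both wavelengths, both set SO2
    levels, all three compensation approaches, at reduced photon count."""
    config = ExperimentConfig(n_photons=N_PHOTONS_PIPELINE, seed=1)
    return run_experiment(config)
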