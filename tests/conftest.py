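import numpy as np
import pytest

import cartspec as cs
from cartspec.pipeline import (
    PipelineConfig,
    analyze_chemistry,
    build_data_matrix,
    run_networks,
)

SESSION_SEED = 1234


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic study: 2 groups x 5 animals x 3 zones, 64x64 cubes."""
    return PipelineConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def study_analysis(default_config):
    """Full chemistry pipeline (generate -> QC -> preprocess -> maps -> stats)."""
    return analyze_chemistry(default_config)


@pytest.fixture(scope="session")
def data_matrix(default_config, study_analysis):
    return build_data_matrix(default_config, study_analysis["matrix_entries"])


@pytest.fixture(scope="session")
def networks(default_config, data_matrix):
    """Trained MLP + SOM + sensitivity on the default study matrix."""
    return run_networks(default_config, data_matrix)


@pytest.fixture
def small_generator():
    """A fast low-noise cube configuration for unit tests."""
    return cs.GeneratorConfig(pixels_x=12, pixels_y=12, noise_sd=0.004, seed=7)


@pytest.fixture
def sz_control_cube(small_generator):
    profiles = cs.default_profiles()
    return cs.generate_cube(small_generator, profiles[("SZ", "C")], cs.default_bands("SZ"))
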