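import numpy as np
import pytest

from proteopower import prep
from proteopower.synthdata import CvCurveParams, SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """Default 6-patient / 3-prep / 3-run design, 300 proteins, no missing."""
    cfg = SyntheticConfig(n_proteins=300, seed=42, missing_max_rate=0.0)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_log2(small_study):
    matrix, metadata, truth = small_study
    log2m = prep.log2_transform(prep.normalize_total_area(matrix))
    return log2m, metadata, truth


@pytest.fixture(scope="session")
def null_study():
    """Zero-effect study: no DE, no batch, no patient effects, flat noise only."""
    cfg = SyntheticConfig(
        n_proteins=400,
        seed=7,
        de_fraction=0.0,
        patient_sd=0.0,
        prep_noise_sd=0.0,
        prep_batch_sd_location=0.0,
        run_noise_sd=0.0,
        missing_max_rate=0.0,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def null_log2(null_study):
    matrix, metadata, truth = null_study
    log2m = prep.log2_transform(prep.normalize_total_area(matrix))
    return log2m, metadata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
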