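import numpy as np
import pytest

from mpnflux import datasets
from mpnflux.synthetic import SimConfig


@pytest.fixture
def quiet_cfg() -> SimConfig:
    """Zero-noise configuration: every estimator should be exact on it."""
    return SimConfig(noise_cv=0.0, assay_noise_sd=0.0, seed=0)


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture
def budget_inputs() -> dict:
    return datasets.reported_budget_inputs()


@pytest.fixture
def survey_fixture():
    """Published survey table plus its reconstructed alignments."""
    return (datasets.phn_survey_alignments(), datasets.phn_survey_metadata(),
            datasets.reference_strain_ids(), datasets.survey_totals_by_ocean())
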