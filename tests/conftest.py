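import numpy as np
import pandas as pd
import pytest

from soilrisk import (
    default_reference_set,
    panel_from_arrays,
    substitute_nondetects,
)
from soilrisk.references import SURVEY_SUMMARY
from soilrisk.synthetic_data import default_source_model, generate_panel


@pytest.fixture(scope="session")
def refs():
    return default_reference_set()


@pytest.fixture(scope="session")
def mean_panel():
    """Single pseudo-sample whose concentrations equal the reference survey
    element means."""
    row = SURVEY_SUMMARY["mean"].to_numpy()[None, :]
    return panel_from_arrays(row)


@pytest.fixture(scope="session")
def synthetic_survey():
    """Default 84-sample synthetic survey (panel, truth), non-detects
    substituted."""
    model = default_source_model()
    panel, truth = generate_panel(model)
    return substitute_nondetects(panel), truth, model


@pytest.fixture(scope="session")
def recovery_survey():
    """Larger (n=200) synthetic survey used for factor-recovery checks."""
    model = default_source_model(n_samples=200, seed=7)
    panel, truth = generate_panel(model)
    return substitute_nondetects(panel), truth, model
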