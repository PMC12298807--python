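import pytest

from tepqueue import DemandModel, generate_log


@pytest.fixture(scope="session")
def default_model() -> DemandModel:
    """The calibrated single-district demand: 3.96/day, 24.6 min."""
    return DemandModel()


@pytest.fixture(scope="session")
def one_year_log(default_model):
    """One 365-day synthetic log at default parameters, fixed seed."""
    return generate_log(default_model, horizon_days=365, seed=20180101)
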