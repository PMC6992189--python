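import pytest

from ohibc.engine import run_assessment
from ohibc.models import GOAL_TREE, default_models
from ohibc.synth import SyntheticSpec, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (8 regions, 2001-2016, realistic noise)."""
    return generate_study(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def assessment(study):
    bundle, params, config, _expected = study
    return run_assessment(bundle, default_models(params), GOAL_TREE, config)


@pytest.fixture(scope="session")
def perfect_assessment():
    """All inputs at reference, zero pressures: every score should be 1."""
    bundle, params, config, expected = generate_study(SyntheticSpec(seed=1, perfect=True))
    return run_assessment(bundle, default_models(params), GOAL_TREE, config), expected
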