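import pytest

from nutricost.pipeline import run_costing
from nutricost.synthetic import SynthConfig, analysis_config_for, generate_ledger


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def analysis_config(synth_config):
    return analysis_config_for(synth_config)


@pytest.fixture(scope="session")
def ledger(synth_config):
    return generate_ledger(synth_config)


@pytest.fixture(scope="session")
def result(ledger, analysis_config):
    """Full pipeline run on the default synthetic ledger."""
    return run_costing(ledger, analysis_config)
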