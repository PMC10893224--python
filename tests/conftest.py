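import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic pipeline run at the default study scale."""
    from cnidotox import SimConfig, run_pipeline
    return run_pipeline(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run.truth
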