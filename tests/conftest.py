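from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from consynt.simulate import paper_count_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_fixture():
    """Deterministic dataset reproducing the study's printed marginal counts."""
    return paper_count_fixture()


@pytest.fixture(scope="session")
def paper_fixture_dir(tmp_path_factory) -> Path:
    """The same fixture written to disk with a ready-to-run config.yaml."""
    out = tmp_path_factory.mktemp("paper_fixture")
    paper_count_fixture(out_dir=out)
    return out
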