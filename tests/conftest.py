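import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genecollapse import fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """The two-gene / five-individual worked example, with paired VCF."""
    return fixtures.toy_dataset(tmp_path_factory.mktemp("toy"), include_vcf=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)
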