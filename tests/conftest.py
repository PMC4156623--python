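import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


@pytest.fixture(scope="session")
def adapter():
    return ADAPTER


@pytest.fixture(scope="session")
def bundle():
    """A small synthetic reference set shared across tests."""
    from tsrna.synthetic import ReferenceConfig, build_reference_set

    return build_reference_set(ReferenceConfig(genome_length=30_000, n_trna=6), seed=11)


@pytest.fixture(scope="session")
def library(bundle, adapter):
    """A default-model library with ground truth."""
    from tsrna.synthetic import FragmentModel, simulate_library

    return simulate_library(bundle, FragmentModel(), n_reads=800, adapter=adapter, seed=5)
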