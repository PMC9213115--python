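import pytest
from hypothesis import settings, HealthCheck

from deglib import DesignSpec, optimize_template, uniprot_target
from deglib.constants import AA_LETTERS, EARLY_ALPHABET

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec20():
    return DesignSpec(alphabet=frozenset(AA_LETTERS), target=uniprot_target())


@pytest.fixture(scope="session")
def spec10():
    return DesignSpec(alphabet=EARLY_ALPHABET, target=uniprot_target(EARLY_ALPHABET))


@pytest.fixture(scope="session")
def template20(spec20):
    return optimize_template(spec20, seed=11)


@pytest.fixture(scope="session")
def template10(spec10):
    return optimize_template(spec10, seed=11)
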