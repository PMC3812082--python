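import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from fluxmut import generate_mutant_sequences, make_reporter_reference


@pytest.fixture(scope="session")
def reporter_reference():
    """A 1.77-kb random reporter ORF with six planted direct-repeat pairs."""
    return make_reporter_reference(length=1771, seed=11)


@pytest.fixture(scope="session")
def synthetic_isolates(reporter_reference):
    """1,000 mutant isolates drawn from the default spectrum."""
    reference, registry = reporter_reference
    return generate_mutant_sequences(
        reference, 1000, seed=12, repeat_registry=registry
    )
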