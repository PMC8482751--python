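import pytest

from fiberex import fixtures


@pytest.fixture(scope="session")
def bundle():
    """The standard synthetic-input bundle, one per session."""
    return fixtures.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def fiber3_states(bundle):
    """A thinned fiber-3-like surrogate state block (many defects)."""
    return bundle["surrogate_triplet"][3].states[::20][:100]
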