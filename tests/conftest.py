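import pytest

from odortunnel import generate_fixtures


@pytest.fixture(scope="session")
def ensemble():
    """Seeded random ensemble of odorants with in-gap probe energies."""
    return generate_fixtures(seed=20260921, n=150)
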