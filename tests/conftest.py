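import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_recipient():
    """A 60-gene recipient genome shared by cheap unit tests."""
    from shadowcaster.simulate import make_recipient

    return make_recipient(n_genes=60, mean_len_codons=150, seed=7)
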