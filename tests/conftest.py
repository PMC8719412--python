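import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazetag.synthetic import SynthSpec, gen_corpus, gen_dictionary, gen_radicals

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    return SynthSpec(sentences=30, test_sentences=10, seed=11)


@pytest.fixture(scope="session")
def small_world(small_spec):
    """A small synthetic dataset shared across tests: (spec, full dictionary,
    scheme, train corpus, test corpus, radical table)."""
    full, scheme = gen_dictionary(small_spec)
    train, test = gen_corpus(small_spec, full)
    radicals = gen_radicals(small_spec)
    return small_spec, full, scheme, train, test, radicals


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
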