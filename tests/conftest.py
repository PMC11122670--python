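import numpy as np
import pytest

from circlocus.synthetic import (SyntheticLocusSpec, make_locus, mirror_bundle,
                                 tulp4_mimic_bundle)


@pytest.fixture(scope="session")
def mimic():
    """The engineered Tulp4-mimic locus used across acceptance-style tests."""
    return tulp4_mimic_bundle(0)


@pytest.fixture(scope="session")
def bundle(mimic):
    return mimic.bundle


@pytest.fixture(scope="session")
def minus_bundle(bundle):
    return mirror_bundle(bundle)


@pytest.fixture(scope="session")
def generic_bundle():
    """A plain synthetic locus with a couple of planted RCMs."""
    return make_locus(SyntheticLocusSpec(
        seed=7, planted_rcms=((200, 0.9, 50, 80), (100, 1.0, 500, 600))))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
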