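import numpy as np
import pytest

from teloepi import synthetic as syn
from teloepi.motif import TELOMERE_MOTIF


@pytest.fixture(scope="session")
def motif():
    return TELOMERE_MOTIF


@pytest.fixture(scope="session")
def small_refs():
    """Two short synthetic subtelomeric arms (2 kb, 10-unit tracts)."""
    cfg = syn.SubtelomereSim(
        n_arms=2, length=2000, tract_units=10, n_interstitial=1, interstitial_units=3
    )
    refs, truth = syn.simulate_subtelomeres(cfg, seed=7)
    return refs, truth


@pytest.fixture(scope="session")
def region_1l0():
    return syn.region_1l0()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
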