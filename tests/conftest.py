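import numpy as np
import pytest

from profalign import StructureProfile, gen_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile():
    return StructureProfile("toy", [0.8, -0.3, 0.1, -1.2, 0.5])


@pytest.fixture
def structured_pair():
    """A structured profile and a mildly perturbed copy of it."""
    from profalign import perturb_profile

    p = gen_profile(300, stem_density=0.5, seed=42, id="orig")
    q = perturb_profile(p, noise_sd=0.1, seed=43)
    return p, q


def random_profile(rng, n, id="p"):
    return StructureProfile(id, rng.normal(size=n))
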