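import numpy as np
import pytest

from ctslider.phantom import PhantomSpec, generate_cohort, generate_phantom_volume


@pytest.fixture(scope="session")
def phantom_case():
    """One positive phantom at test resolution."""
    return generate_phantom_volume(PhantomSpec(image_size=64, seed=7,
                                               fibrosis_severity=0.9))


@pytest.fixture(scope="session")
def small_cohort():
    """A dozen jittered phantoms, both classes."""
    return generate_cohort(12, 0.5, base_spec=PhantomSpec(image_size=64), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
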