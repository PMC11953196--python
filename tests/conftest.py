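import numpy as np
import pytest

from macuhole.index import compute_pra
from macuhole.synthetic.cohorts import default_cohort_spec, generate_cohort
from macuhole.synthetic.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def circular_phantom():
    """Noise-free circular phantom: lumen r 0.20 mm, ring width 0.10 mm, 10 µm/px."""
    spec = PhantomSpec()
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def default_cohort_38():
    return generate_cohort(default_cohort_spec(n=38, seed=11))


@pytest.fixture(scope="session")
def default_cohort_2000():
    return generate_cohort(default_cohort_spec(n=2000, seed=2))


@pytest.fixture()
def small_area_cohort():
    return [
        compute_pra(0.30, 0.15),
        compute_pra(0.56, 0.53),
        compute_pra(0.06, 0.03),
        compute_pra(0.40, 0.20),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
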