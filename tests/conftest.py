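import numpy as np
import pytest

from uoastats.datasets import DesignLayout, load_fixture
from uoastats.design import simulate_nested_dataset
from uoastats.glmm import fit_logistic_glmm
from uoastats.lmm import VarianceComponents, fit_nested_lmm


@pytest.fixture(scope="session")
def lymph_size():
    return load_fixture("lymph_size")


@pytest.fixture(scope="session")
def lymph_count():
    return load_fixture("lymph_count")


@pytest.fixture(scope="session")
def size_fit(lymph_size):
    """Full three-level REML fit of the size dataset (shared; read-only)."""
    return fit_nested_lmm(lymph_size, levels=("subject", "sample"))


@pytest.fixture(scope="session")
def size_fit_subject_only(lymph_size):
    return fit_nested_lmm(lymph_size, levels=("subject",))


@pytest.fixture(scope="session")
def count_glmm(lymph_count):
    """Laplace fit of the binomial mixed model (shared; read-only)."""
    return fit_logistic_glmm(lymph_count, n_quad=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def example1_layout():
    """2 groups x 6 subjects x 2 samples x 3 slices."""
    return DesignLayout(2, 6, 2, 3)


@pytest.fixture(scope="session")
def example1_components():
    return VarianceComponents(0.4, 0.2, 0.1)


@pytest.fixture(scope="session")
def simulated_balanced(example1_layout, example1_components):
    return simulate_nested_dataset(example1_layout, 0.5, example1_components, seed=11)
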