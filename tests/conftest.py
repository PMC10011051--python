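import numpy as np
import pytest

from strokecpm import SyntheticSpec, generate_connectomes_direct


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_cohort():
    """Seed-fixed cohort with a strong planted pos-edge effect.

    N=40 subjects, M=20 nodes, 5 planted edges, effect 1.0, noise 0.5 —
    the reference recovery scenario used across the regression tests.
    """
    spec = SyntheticSpec(n_subjects=40, n_nodes=20, n_planted=5,
                         effect_size=1.0, noise_sd=0.5,
                         base_connectivity_sd=0.3, seed=7)
    connectomes, behavior, truth = generate_connectomes_direct(spec)
    return spec, connectomes, behavior, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Seed-fixed cohort with no edge-behavior link (effect_size=0)."""
    spec = SyntheticSpec(n_subjects=20, n_nodes=10, n_planted=3,
                         effect_size=0.0, seed=99)
    connectomes, behavior, truth = generate_connectomes_direct(spec)
    return spec, connectomes, behavior, truth
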