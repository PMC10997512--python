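import numpy as np
import pytest

from cmlstate.potentials import CircuitParams, PotentialModel
from cmlstate.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def circuit_params():
    return CircuitParams.reference()


@pytest.fixture(scope="session")
def quintic():
    """Symmetric quintic-gradient landscape with known critical points."""
    return PotentialModel(kind="quintic", a=1.0,
                          critical_points=[2.0, 1.0, 0.0, -1.0, -2.0])


@pytest.fixture(scope="session")
def planted_potential():
    from cmlstate.synthetic import default_true_potential
    return default_true_potential()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-gene-count cohort for fast unit tests (full design sizes)."""
    cfg = SyntheticConfig(seed=11, n_genes=3000)
    counts, table, truth = generate_cohort(cfg)
    return cfg, counts, table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (study-design defaults)."""
    cfg = SyntheticConfig(seed=1)
    counts, table, truth = generate_cohort(cfg)
    return cfg, counts, table, truth
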