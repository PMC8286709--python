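import numpy as np
import pytest

from habmod.data import GeneratorConfig, generate_dataset


def small_cells(contrasts=("luminance", "color"), cohorts=("4M", "7M", "10M"),
                hab=(1, 3, 5, 7), n=2):
    return {(co, ct, d): n for co in cohorts for ct in contrasts for d in hab}


@pytest.fixture(scope="session")
def tiny_dataset():
    """Twelve gamma-trend infants in two cells; smallest design that the
    hierarchical model fits comfortably."""
    cfg = GeneratorConfig(
        cell_sizes={("7M", "luminance", 3): 6, ("4M", "color", 5): 6},
        dropout_hazard=0.0,
    )
    return generate_dataset(cfg, seed=101)


@pytest.fixture(scope="session")
def small_dataset():
    """24 gamma-trend infants across contrasts, cohorts and habituation counts."""
    cfg = GeneratorConfig(cell_sizes=small_cells(n=1), dropout_hazard=0.0)
    return generate_dataset(cfg, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
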