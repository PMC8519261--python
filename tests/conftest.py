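import numpy as np
import pytest

from ctxpls import SyntheticScenario, make_parcellation


@pytest.fixture
def small_scenario():
    """10 regions, 60 genes, 3 donors: fast but non-trivial."""
    return SyntheticScenario(
        n_regions=10,
        n_genes=60,
        n_donors=3,
        n_patients=40,
        n_controls=50,
        seed=11,
    )


@pytest.fixture
def small_parcellation(small_scenario):
    return make_parcellation(small_scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
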