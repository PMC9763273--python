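import numpy as np
import pytest

from filab import CohortConfig, default_registry, generate_cohort, score_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def scored_cohort(registry):
    """Mid-sized synthetic cohort with FI-Lab scores and quartiles assigned."""
    cfg = CohortConfig(n_patients=1500, seed=7)
    return score_table(generate_cohort(cfg, registry), registry)


@pytest.fixture()
def normal_items(registry):
    """A complete item mapping with every value inside its reference range."""
    out = {}
    for it in registry:
        if it.value_kind == "dipstick":
            out[it.name] = it.normal_category
        elif it.lower is not None and it.upper is not None:
            out[it.name] = 0.5 * (it.lower + it.upper)
        elif it.upper is not None:
            out[it.name] = it.upper / 2
        else:
            out[it.name] = it.lower + 1.0
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
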