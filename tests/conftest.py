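import numpy as np
import pandas as pd
import pytest

import patmix as pm


@pytest.fixture(scope="session")
def gen_config():
    """Default-condition generator: n=20,000, cell rates (0.16, 0.25, 0.14, 0.22)."""
    return pm.GeneratorConfig(n_patients=20_000, seed=7)


@pytest.fixture(scope="session")
def complete_registry(gen_config):
    return pm.generate_registry(gen_config)


@pytest.fixture(scope="session")
def masked_registry(gen_config, complete_registry):
    table, mask = pm.apply_missingness(complete_registry, gen_config)
    return table, mask


@pytest.fixture(scope="session")
def mar_stack(masked_registry):
    """MAR chained-equations stack at the default m=10, 10 cycles."""
    table, _ = masked_registry
    return pm.fcs_impute(table, pm.FcsConfig(m=10, cycles=10, seed=7))


@pytest.fixture(scope="session")
def demo_prior():
    return pm.ElicitedPrior.from_arrays(
        pm.DEMO_ELICITED_MEANS, pm.DEMO_ELICITED_VARIANCES, K=6
    )


@pytest.fixture(scope="session")
def demo_spec(demo_prior):
    return pm.fit_dirichlet(demo_prior)
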