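import dataclasses

import numpy as np
import pytest

from exprvar.simulate import SyntheticSpec, generate_cohorts, null_spec


@pytest.fixture(scope="session")
def small_cohorts():
    """A small paired-cohort simulation with DV and DE structure."""
    spec = dataclasses.replace(SyntheticSpec(), n_genes=600, seed=5)
    m1, g1, m2, g2, truth = generate_cohorts(spec)
    return {"spec": spec, "m1": m1, "g1": g1, "m2": m2, "g2": g2, "truth": truth}


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no DV and no DE genes (both groups exchangeable)."""
    spec = null_spec(n_genes=600, seed=9)
    m1, g1, _, _, truth = generate_cohorts(spec)
    return {"spec": spec, "m": m1, "groups": g1, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
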