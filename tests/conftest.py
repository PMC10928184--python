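import numpy as np
import pandas as pd
import pytest

from epiregulome import generate_cohorts, make_config, preprocess_study


@pytest.fixture(scope="session")
def planted_study():
    """One cohort (30 disease + 30 control), two planted modules over a
    200-gene background; shared across tests that need realistic expression."""
    cfg = make_config(
        n_genes=250,
        cohorts=[("A", 30, 30)],
        module_sizes=[25, 30],
        r2_disease=0.7,
        r2_control=0.1,
        seed=20_240_101,
    )
    counts, meta, truth = generate_cohorts(cfg)
    study = preprocess_study(counts, meta)
    return study, truth


@pytest.fixture(scope="session")
def disease_control(planted_study):
    study, truth = planted_study
    d = study.cohort_samples("A", "disease")
    c = study.cohort_samples("A", "control")
    return study.expr[d], study.expr[c], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
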