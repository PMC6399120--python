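from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cgas.simulate import (
    CovariateSpec,
    SimConfig,
    SnpSpec,
    paper_template_config,
    simulate_cohort,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190226)


def small_config(seed: int = 5, n: int = 500, **kw) -> SimConfig:
    """A small clean cohort: 4 SNPs (one dominant effect), no missingness."""
    defaults = dict(
        n_subjects=n,
        case_fraction=0.5,
        seed=seed,
        covariates=CovariateSpec(
            female_frac=0.5, age_mean=55, age_sd=10, noncaucasian_frac=0.1,
            diabetes_prev=0.2, hypertension_prev=0.5,
            beta_hypertension=np.log(3.0), beta_diabetes=np.log(1.8),
        ),
        snp_specs=[
            SnpSpec("rsA", maf=0.3, model="dominant", beta=np.log(1.8)),
            SnpSpec("rsB", maf=0.25, model="additive", beta=0.0),
            SnpSpec("rsC", maf=0.4, model="additive", beta=0.0),
            SnpSpec("rsD", maf=0.15, model="additive", beta=0.0),
        ],
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def template_cohort():
    """One study-template cohort shared by QC/pipeline-level tests."""
    return simulate_cohort(paper_template_config(seed=11))
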