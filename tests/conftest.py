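import numpy as np
import pandas as pd
import pytest

from endoclass.phenotypes import AnalysisCohort
from endoclass.simulate import GenePanel, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A quick, fully-featured cohort config shared across tests."""
    return SimulationConfig(
        n_samples=2000,
        seed=11,
        vus_fraction=0.2,
        conflicting_fraction=0.05,
        absent_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from endoclass.simulate import generate_cohort

    return generate_cohort(small_config)


def make_cohort(phenotype, covariates=None, trait="ldl_c") -> AnalysisCohort:
    """Hand-build an AnalysisCohort without exclusions, for model tests."""
    pheno = pd.Series(np.asarray(phenotype, dtype=float),
                      index=[f"S{i}" for i in range(len(phenotype))],
                      name=trait)
    if covariates is None:
        cov = pd.DataFrame(index=pheno.index)
    else:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float), index=pheno.index)
        cov.columns = [f"c{i}" for i in range(cov.shape[1])]
    return AnalysisCohort(
        trait=trait, phenotype=pheno, covariates=cov,
        exclusion_log=pd.DataFrame(columns=["sample_id", "reason"]),
        n_input=len(pheno), n_final=len(pheno),
    )


@pytest.fixture
def three_effect_panel():
    """A tiny panel config with three noise-free point effects {0, 10, -5}."""
    config = SimulationConfig(
        n_samples=2000,
        seed=5,
        noise_sd=0.0,
        covariate_effects={},
        panels=[GenePanel("LDLR", {"pathogenic": 1, "likely_pathogenic": 1,
                                   "benign": 1})],
        category_effect_means={"pathogenic": 10.0, "likely_pathogenic": -5.0,
                               "vus_like": 0.0, "conflicting_like": 0.0,
                               "likely_benign": 0.0, "benign": 0.0},
        category_effect_sds={k: 0.0 for k in
                             ["pathogenic", "likely_pathogenic", "vus_like",
                              "conflicting_like", "likely_benign", "benign"]},
    )
    return config
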