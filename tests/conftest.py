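import numpy as np
import pandas as pd
import pytest

from tte.pipeline import AnalysisConfig, build_cohort
from tte.synthetic_registry import SyntheticConfig, generate_registry

RAW_COVARIATES = ("age", "female", "nstemi", "sbp", "egfr", "ldl")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_individuals=1500, seed=11, treatment_effect=-0.1,
        adherence_stop_logit=-3.8, crossover_start_logit=-5.0,
        indication_rate=0.005, contraindication_rate=0.002,
        noneligible_fraction={"age": 0.04, "low_lvef": 0.04,
                              "prior_indication": 0.04, "prior_acei_arb": 0.03,
                              "unemployed": 0.02},
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_registry(small_config)


@pytest.fixture(scope="session")
def small_analysis_config(small_config) -> AnalysisConfig:
    return AnalysisConfig(synthetic=small_config, weight_covariates=RAW_COVARIATES)


@pytest.fixture(scope="session")
def small_cohort(small_bundle, small_analysis_config):
    cohort, tally = build_cohort(small_bundle, small_analysis_config)
    return cohort, tally
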