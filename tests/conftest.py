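import numpy as np
import pandas as pd
import pytest

from methscore.io import MethylationMatrix, MwasSummary, PhenotypeTable
from methscore.simulate import (
    CohortConfig,
    MddModel,
    TraitConfig,
    simulate_cohort,
    simulate_mwas,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One-trait cohort with known ground truth, reused across tests."""
    cfg = CohortConfig(
        n_samples=600,
        n_cpgs=300,
        traits=(TraitConfig("bmi", 20, 0.3),),
        mdd=MddModel(prevalence=0.2, trait_weights={"bmi": 0.6}),
        seed=7,
    )
    matrix, pheno, truth = simulate_cohort(cfg)
    return matrix, pheno, truth


@pytest.fixture(scope="session")
def small_mwas(small_cohort):
    _, _, truth = small_cohort
    return simulate_mwas(truth, "bmi", est_noise_sd=0.1, n_null_cpgs=80, seed=11)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.05, 0.95, size=(8, 5))
    return MethylationMatrix(
        pd.DataFrame(
            vals,
            index=[f"S{i}" for i in range(8)],
            columns=[f"cg{i:08d}" for i in range(5)],
        ),
        "beta",
    )


@pytest.fixture()
def tiny_mwas():
    return MwasSummary(
        "demo",
        pd.DataFrame(
            {
                "cpg": [f"cg{i:08d}" for i in range(5)],
                "weight": [0.5, -1.2, 0.3, 2.0, -0.7],
                "p": [1e-9, 0.004, 0.03, 0.2, 0.6],
            }
        ),
    )
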