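import numpy as np
import pandas as pd
import pytest

from rvcollapse.io import reference_dict
from rvcollapse.simulate import SimulationConfig, generate_reference, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with a strong PTV effect gene, shared across tests."""
    config = SimulationConfig(
        n_cases=300,
        n_controls=3000,
        n_genes=12,
        cumulative_ptv_allele_freq=2e-3,
        gene_effects={"GENE0001": 10.0},
        seed=50,
    )
    samples, sites, calls = simulate_cohort(config)
    reference = reference_dict(generate_reference(sites, seed=43))
    return {
        "config": config,
        "samples": samples,
        "sites": sites,
        "calls": calls,
        "reference": reference,
    }


@pytest.fixture()
def phenotype(small_cohort):
    s = small_cohort["samples"]
    return pd.Series(s["phenotype"].to_numpy(), index=s["sample_id"].to_numpy())
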