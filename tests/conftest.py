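"""Shared fixtures: small synthetic NAM populations and trials."""

import numpy as np
import pandas as pd
import pytest

import namgei as ng


@pytest.fixture(scope="session")
def small_geno():
    """4 families x 30 RILs x 40 markers; deterministic."""
    design = ng.NamDesign(
        n_families=4, n_rils_per_family=30, n_markers=40, n_chromosomes=4, seed=1
    )
    return ng.simulate_genotypes(design)


@pytest.fixture(scope="session")
def mid_geno():
    """10 families x 50 RILs x 100 markers for power-style checks."""
    design = ng.NamDesign(
        n_families=10, n_rils_per_family=50, n_markers=100, n_chromosomes=10, seed=3
    )
    return ng.simulate_genotypes(design)


@pytest.fixture
def trial5():
    return ng.TrialDesign(
        environments=["E1", "E2", "E3", "E4", "E5"],
        env_effects=[2500.0, 3000.0, 3500.0, 4000.0, 4500.0],
        residual_sd=200.0,
        block_sd=50.0,
    )


@pytest.fixture
def noiseless_trial5():
    return ng.TrialDesign(
        environments=["E1", "E2", "E3", "E4", "E5"],
        env_effects=[2500.0, 3000.0, 3500.0, 4000.0, 4500.0],
        residual_sd=0.0,
        block_sd=0.0,
    )


def make_pheno(records):
    """Build a phenotype table from (ril, env, block, yield, is_check) tuples."""
    return pd.DataFrame(records, columns=["ril_id", "env", "block", "yield", "is_check"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
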