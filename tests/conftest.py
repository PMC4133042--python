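"""Shared fixtures: small simulated panels with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from imaging_greml import GRM, SimConfig, compute_grm, simulate_genotypes
from imaging_greml.synth import simulate_phenotype


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_subjects=200, n_snps=500, n_causal=50,
                     maf_range=(0.05, 0.4), target_h2=0.5, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """200 x 500 genotype panel, no missingness."""
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return compute_grm(small_panel)


@pytest.fixture(scope="session")
def h2_half_trait(small_panel):
    """A single polygenic trait with realized VG/Vp = 0.5 plus its truth."""
    rng = np.random.default_rng(7)
    y, truth = simulate_phenotype(small_panel, n_causal=50, h2=0.5, rng=rng)
    return y, truth


def identity_grm(n: int) -> GRM:
    ids = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)]}
    )
    return GRM(np.eye(n), np.full((n, n), 100, dtype=int), ids)
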