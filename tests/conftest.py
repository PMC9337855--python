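import numpy as np
import pandas as pd
import pytest

from thermogrowth.config import SimConfig
from thermogrowth.io import phenotypes_to_series
from thermogrowth.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study: 12 accessions x 2 experiments x 2 temps."""
    cfg = SimConfig.desk_scale(seed=42, n_accessions=12, n_experiments=2)
    truth, pheno, plant_truth = simulate_dataset(cfg)
    return cfg, truth, pheno, plant_truth


@pytest.fixture(scope="session")
def small_series(small_dataset):
    _, _, pheno, _ = small_dataset
    return phenotypes_to_series(pheno)


@pytest.fixture(scope="session")
def stage2_fit(small_series):
    from thermogrowth.nlmm import fit_stage2

    return fit_stage2(small_series, car1=True, seed=0)


@pytest.fixture(scope="session")
def panel_truth():
    """Accession-level panel at full size (no plant series): genotypes,
    climate, traits for 249 accessions."""
    from thermogrowth.simulate import simulate_climate_and_traits, simulate_genotypes

    cfg = SimConfig(seed=7)
    g, pops = simulate_genotypes(cfg)
    truth = simulate_climate_and_traits(cfg, g, pops)
    return cfg, truth


@pytest.fixture(scope="session")
def panel_kinship(panel_truth):
    from thermogrowth.quantgen import kinship_centered

    _, truth = panel_truth
    return kinship_centered(truth.genotypes)
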