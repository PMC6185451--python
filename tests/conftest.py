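import numpy as np
import pandas as pd
import pytest

from icld.genotype_io import GenotypeMatrix, recompute_pop_mafs, classify_maf
from icld.synthetic_data import BatchSimConfig, inject_errors, simulate_genotypes


@pytest.fixture(scope="session")
def clean_small():
    """Small clean dataset: 60 samples, 60 variants on 4 chromosomes."""
    cfg = BatchSimConfig(
        n_individuals=60, n_variants=60, n_chromosomes=4, seed=11
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def error_dataset():
    """Batch-error dataset with known truth, strong enough to detect.

    100 samples, 400 variants on 8 chromosomes, low-frequency spectrum,
    errors at 1% of sites in 10 of 20 batch members.
    """
    cfg = BatchSimConfig(
        n_individuals=100,
        n_variants=400,
        n_chromosomes=8,
        maf_spectrum="beta",
        maf_low=0.01,
        batch_fraction=0.2,
        affected_fraction=0.5,
        error_site_fraction=0.01,
        seed=7,
    )
    clean = simulate_genotypes(cfg)
    noisy, truth = inject_errors(clean, cfg)
    return clean, noisy, truth


@pytest.fixture(scope="session")
def error_links(error_dataset):
    """Step-1 output (scan, permutations, fdr, links) for the error dataset."""
    from icld.pipeline import PipelineConfig, step1_links

    _clean, noisy, _truth = error_dataset
    return step1_links(noisy, PipelineConfig(seed=7))


@pytest.fixture()
def two_pop_matrix():
    """Hand-built two-population matrix with a missing call."""
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=(20, 12)).astype(np.int8)
    g[0, 0] = -1
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6 + ["chr2"] * 6,
            "pos": list(range(100, 700, 100)) * 2,
            "ref": ["A"] * 12,
            "alt": ["G"] * 12,
            "minor_is_alt": [True] * 12,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(20)],
            "population": ["P1"] * 10 + ["P2"] * 10,
        }
    )
    m = GenotypeMatrix(genotypes=g, variants=variants, samples=samples)
    recompute_pop_mafs(m)
    classify_maf(m)
    return m
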