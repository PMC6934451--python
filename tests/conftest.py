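import numpy as np
import pytest

from r2parse import association, simulate
from r2parse.simulate import SimulationSpec


@pytest.fixture(scope="session")
def roi_sim():
    """A 40-SNP ROI (8 independent 5-SNP blocks) with two causal SNPs."""
    dataset, truth = simulate.simulate_roi(
        8, 5, {0: 0.25, 20: 0.10}, seed=3, n_individuals=1000
    )
    return dataset, truth


@pytest.fixture(scope="session")
def roi_profile(roi_sim):
    dataset, _ = roi_sim
    return association.estimate_per_snp(dataset)


@pytest.fixture(scope="session")
def noiseless_sim():
    """One causal SNP, zero residual noise: expression is exactly a*g."""
    block = simulate.random_haplotype_spec(4, 7, alpha=0.5, min_maf=0.1)
    spec = SimulationSpec(
        haplotypes=block,
        causal_idx=[1],
        effects=[0.8],
        noise_sd=0.0,
        n_individuals=500,
        seed=7,
    )
    return simulate.simulate_dataset(spec)


@pytest.fixture(scope="session")
def noiseless_profile(noiseless_sim):
    dataset, _ = noiseless_sim
    return association.estimate_per_snp(dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
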