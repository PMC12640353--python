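import numpy as np
import pandas as pd
import pytest

from flockscape.genio import GenotypePanel
from flockscape.sim import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """4 breeds x 12+12 samples, 2 chromosomes x 150 SNPs."""
    return SimConfig(seed=7, n_breeds=4, samples_per_breed_per_cohort=12,
                     n_chrom=2, snps_per_chrom=150, missing_rate=0.02)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = simulate_panel(small_config)
    return panel, truth


def make_panel(genotypes, chrom=None, bp=None, breeds=None, cohorts=None,
               spacing=10_000) -> GenotypePanel:
    """Hand-rolled panel from a genotype matrix for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    chrom = chrom if chrom is not None else np.ones(m, dtype=int)
    bp = bp if bp is not None else (np.arange(m) + 1) * spacing
    breeds = breeds if breeds is not None else ["X"] * n
    cohorts = cohorts if cohorts is not None else ["current"] * n
    samples = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "breed": breeds, "cohort": cohorts,
        "farm": [f"f{i % 3}" for i in range(n)]})
    snp_map = pd.DataFrame({"snp_id": [f"m{j}" for j in range(m)],
                            "chrom": chrom, "bp": bp})
    return GenotypePanel(samples, g, snp_map)
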