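import numpy as np
import pandas as pd
import pytest

from transloc.config import default_simulation_config
from transloc.simulate import simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by integration-style tests."""
    cfg = default_simulation_config(seed=7, n_snps=400, n_count_loci=1200)
    bundle, truth = simulate_study(cfg)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20210706)


def make_genotype_matrix(genotypes, populations=None, chrom=None, pos=None, systems=None):
    """Helper to assemble a GenotypeMatrix from raw pieces."""
    from transloc.containers import GenotypeMatrix

    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    samples = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "population": populations if populations is not None else ["pop1"] * n,
    })
    if systems is not None:
        samples["system"] = systems
    snps = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "snp_id": [f"snp{j}" for j in range(m)],
    })
    return GenotypeMatrix(genotypes, samples, snps)
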