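import numpy as np
import pandas as pd
import pytest

from gwasim import fixtures, genotypes


@pytest.fixture(scope="session")
def fixture_config():
    return fixtures.FixtureConfig(n_diploids=100, n_snps=500, n_blocks=20, n_genes=250, seed=42)


@pytest.fixture(scope="session")
def panel(fixture_config):
    return fixtures.make_panel(fixture_config)


@pytest.fixture(scope="session")
def annotation_bundle(fixture_config, panel):
    genes, sets = fixtures.make_annotation(fixture_config, panel)
    return genes, sets


@pytest.fixture(scope="session")
def small_genotypes(panel):
    return genotypes.simulate_genotypes(panel, 400, seed=7)


def make_genotypes(dosages, chrom="1", pos=None, ids=None):
    """Build a GenotypeMatrix straight from a dosage array (tests only)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    pos = pos if pos is not None else 1000 + 100 * np.arange(m)
    ids = ids if ids is not None else [f"snp{j + 1}" for j in range(m)]
    freq = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * m,
            "pos": pos,
            "id": ids,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return genotypes.GenotypeMatrix(
        variants=variants, dosages=dosages, sample_ids=[f"s{i + 1}" for i in range(n)]
    )
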