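import numpy as np
import pandas as pd
import pytest

from qtlmodules.containers import GenotypeMatrix


def make_genotypes(dosages: np.ndarray, positions=None, chrom="1") -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from a raw dosage array (samples x variants)."""
    n, m = dosages.shape
    vids = [f"v{j + 1:04d}" for j in range(m)]
    sids = [f"s{i + 1:05d}" for i in range(n)]
    if positions is None:
        positions = 1 + np.arange(m) * 10_000
    eaf = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": np.minimum(eaf, 1 - eaf),
        },
        index=vids,
    )
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=sids, columns=vids), variants=variants
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_geno(rng):
    """60 samples x 6 independent variants, maf ~0.4."""
    dosages = rng.binomial(1, 0.4, size=(60, 6)) + rng.binomial(1, 0.4, size=(60, 6))
    return make_genotypes(dosages.astype(float))
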