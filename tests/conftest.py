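import numpy as np
import pandas as pd
import pytest

from driftscan.genodata import MISSING, GenotypeTable


def make_table(genotypes, sources=None, gq=None, chrom="1", pos0=1000, step=1000,
               ref="A", alt="G"):
    """Small GenotypeTable helper: genotypes is (n_samples, n_snps)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if sources is None:
        sources = ["chip"] * n
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos0 + step * np.arange(m),
            "ref": ref,
            "alt": alt,
            "id": [f"snp{i}" for i in range(m)],
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "source": sources}
    )
    return GenotypeTable(variants=variants, samples=samples, genotypes=genotypes,
                         gq=None if gq is None else np.asarray(gq, dtype=float))


@pytest.fixture
def toy_table():
    return make_table([[0, 1, 2], [1, 1, 0], [2, 0, MISSING]])
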