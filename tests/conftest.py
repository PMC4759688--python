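import numpy as np
import pytest

from riskfield.data_io import GenotypeMatrix, compute_maf


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(dosages, genes=None, subject_prefix="S", variant_prefix="v"):
    """Small GenotypeMatrix builder for constructed examples."""
    d = np.asarray(dosages, dtype=np.float64)
    n, m = d.shape
    vids = [f"{variant_prefix}{j + 1}" for j in range(m)]
    gov = {}
    if genes is not None:
        gov = {vid: gene for vid, gene in zip(vids, genes)}
    return GenotypeMatrix(
        d, [f"{subject_prefix}{i + 1}" for i in range(n)], vids, gov, maf=compute_maf(d)
    )


@pytest.fixture
def toy_genotypes():
    # 4 subjects x 3 variants; v3 monomorphic
    return make_genotypes([[0, 1, 0], [1, 1, 0], [2, 0, 0], [2, 1, 0]])
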