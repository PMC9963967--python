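import numpy as np
import pandas as pd
import pytest

from isletmir.io import GenotypeMatrix, VARIANT_COLUMNS


def make_genotypes(dosages, chrom="chr1", pos0=1_000_000, spacing=1_000):
    """Small GenotypeMatrix from a samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    meta = pd.DataFrame(
        [
            (f"v{j}", chrom, pos0 + j * spacing, "A", "G",
             min(dosages[:, j].mean() / 2, 1 - dosages[:, j].mean() / 2))
            for j in range(m)
        ],
        columns=VARIANT_COLUMNS,
    )
    return GenotypeMatrix(dosages, [f"S{i}" for i in range(n)], meta)


@pytest.fixture
def tiny_genotypes():
    return make_genotypes([[0, 1], [1, 2], [2, 0], [1, 1]])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
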