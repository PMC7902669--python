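import numpy as np
import pytest

from popsweep.io import GenotypeMatrix


def random_matrix(rng, n_hap=8, n_sites=40, missing_frac=0.0, chrom="chr1"):
    """Random biallelic matrix with every site guaranteed to have at least
    one called haplotype."""
    calls = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((n_hap, n_sites)) < missing_frac
        # never blank out an entire column
        for j in range(n_sites):
            if mask[:, j].all():
                mask[rng.integers(0, n_hap), j] = False
        calls[mask] = -1
    pos = np.sort(rng.choice(np.arange(1, n_sites * 50), size=n_sites, replace=False))
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_hap)],
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        calls=calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
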