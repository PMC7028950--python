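import numpy as np
import pytest

from hapsweep import HaplotypeMatrix, VariantMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_matrix(alleles, spacing_bp=50_000, chrom="1"):
    """Wrap a raw 0/1 array (rows=haplotypes) with an evenly spaced map."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, L = alleles.shape
    assert n_hap % 2 == 0
    pos = (np.arange(L) + 1) * spacing_bp
    vmap = VariantMap(
        np.asarray([chrom] * L, dtype=object),
        np.asarray([f"s{j}" for j in range(L)], dtype=object),
        pos,
        pos * 1e-6,
    )
    hm = HaplotypeMatrix(alleles, [f"ind{i}" for i in range(n_hap // 2)])
    return hm, vmap


@pytest.fixture
def random_matrix(rng):
    """20 haplotypes x 40 sites, polymorphic everywhere."""
    while True:
        a = (rng.random((20, 40)) < rng.uniform(0.2, 0.8, size=40)).astype(np.uint8)
        f = a.mean(axis=0)
        if ((f > 0) & (f < 1)).all():
            return make_matrix(a)
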