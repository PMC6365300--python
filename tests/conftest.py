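import numpy as np
import pandas as pd
import pytest

from blink import GenotypeData, PhenotypeData


def make_geno(codes, chroms=None, positions=None, ids=None, iids=None):
    codes = np.asarray(codes, dtype=np.int8)
    m, n = codes.shape
    gmap = pd.DataFrame({
        "marker_id": ids or [f"m{i}" for i in range(m)],
        "chromosome": chroms or ["1"] * m,
        "position": positions if positions is not None
        else list(range(1, m + 1)),
    })
    iids = iids or [f"i{j}" for j in range(n)]
    return GenotypeData(codes, gmap, np.asarray(iids, dtype=object))


@pytest.fixture
def small_geno():
    """3 markers x 4 individuals, all codes defined."""
    return make_geno([[0, 1, 2, 0],
                      [2, 2, 1, 0],
                      [0, 0, 1, 1]])


@pytest.fixture
def random_geno():
    """200 markers x 60 individuals with some missing calls."""
    rng = np.random.default_rng(42)
    codes = rng.integers(0, 3, size=(200, 60)).astype(np.int8)
    miss = rng.random(codes.shape) < 0.03
    codes[miss] = -9
    positions = rng.integers(1, 10_000_000, size=200)
    chroms = [f"{c}" for c in rng.integers(1, 6, size=200)]
    return make_geno(codes, chroms=chroms, positions=positions)


@pytest.fixture
def pheno_for(small_geno):
    return PhenotypeData(small_geno.individual_ids, [1.0, 2.0, 3.0, 4.0])
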