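import numpy as np
import pytest

from ebqtl.maps import BinEntry, BinMap, GenotypeMatrix, PhenotypeVector
from ebqtl.simulate import (SimConfig, derive_imf2, make_map, simulate_rils)


@pytest.fixture
def small_map() -> BinMap:
    return BinMap([
        BinEntry("b1", "1", 0.0),
        BinEntry("b2", "1", 3.2),
        BinEntry("b3", "1", 8.4),
        BinEntry("b4", "2", 0.0),
        BinEntry("b5", "2", 12.0),
    ])


@pytest.fixture
def small_genotypes(small_map) -> GenotypeMatrix:
    rng = np.random.default_rng(42)
    codes = rng.integers(0, 3, size=(12, small_map.m)).astype(np.int8)
    ids = [f"ind{t}" for t in range(12)]
    return GenotypeMatrix(codes, ids, small_map.bin_ids)


@pytest.fixture
def imf2_population():
    """A modest IMF2 population with its map (n=120, m=60)."""
    cfg = SimConfig(n_chrom=3, bins_per_chrom=20, n_ril=80, n_cross=120,
                    seed=7)
    rng = np.random.default_rng(7)
    bin_map = make_map(cfg)
    rils = simulate_rils(cfg, bin_map, rng)
    imf2 = derive_imf2(rils, cfg.n_cross, rng=rng)
    return bin_map, imf2


def random_phenotype(n, seed=0, name="trait"):
    rng = np.random.default_rng(seed)
    return PhenotypeVector(name, rng.normal(size=n),
                           [f"IMF2_{t+1}" for t in range(n)])
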