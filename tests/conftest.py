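import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from strainmapqtl.hapmap import GenotypeTable


def random_table(rng: np.random.Generator, n_strains: int, n_variants: int,
                 chroms: tuple[str, ...] = ("1",), max_pos: int = 10_000) -> GenotypeTable:
    """A random homozygous genotype table for oracle-equivalence tests."""
    chrom_of = rng.choice(len(chroms), size=n_variants)
    chrom_col, pos_col = [], []
    for ci, c in enumerate(chroms):
        n = int((chrom_of == ci).sum())
        pos = np.sort(rng.choice(np.arange(1, max_pos + 1), size=n, replace=False))
        chrom_col.extend([c] * n)
        pos_col.extend(pos.tolist())
    n_variants = len(pos_col)
    calls = rng.integers(0, 2, size=(n_strains, n_variants)).astype(np.uint8)
    return GenotypeTable(
        strains=[f"S{i+1:02d}" for i in range(n_strains)],
        chrom=np.array(chrom_col, dtype=object),
        pos=np.array(pos_col, dtype=np.int64),
        ref=np.full(n_variants, "A", dtype=object),
        alt=np.full(n_variants, "T", dtype=object),
        calls=calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return random_table(rng, n_strains=5, n_variants=300, chroms=("1", "2"))
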