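import numpy as np
import pytest

from popdiseq import GenotypeMatrix, SimConfig, SnpMap


def small_panel() -> SnpMap:
    """24 SNPs on 3 chromosomes of 50 Mb, clustered at 2-23 Mb."""
    ids, chroms, pos = [], [], []
    for c in (1, 2, 3):
        for k in range(8):
            ids.append(f"s{c}_{k}")
            chroms.append(c)
            pos.append(int(2e6 + k * 3e6))
    return SnpMap(ids, chroms, np.array(pos, dtype=np.int64))


@pytest.fixture
def small_config() -> SimConfig:
    """A fast, reduced simulation: 3 chromosomes, 30 loci, 4 QTLs."""
    return SimConfig(
        n_chromosomes=3,
        chrom_lengths_bp=(50_000_000,) * 3,
        snp_positions=small_panel(),
        n_snps_total=30,
        n_qtl=4,
        n_minor=16,
        pop_size=60,
        seed=11,
    )


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """4 individuals x 3 SNPs on two chromosomes, one missing call."""
    m = SnpMap(["a", "b", "c"], [1, 1, 2], np.array([100, 2000, 500]))
    dos = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, -1, 2]], dtype=np.int8)
    return GenotypeMatrix(["i1", "i2", "i3", "i4"], dos, m)
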