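import numpy as np
import pytest

from crossacd.types import GenomicInterval


def acd_grid(
    n_chrom: int = 4,
    n_per_chrom: int = 6,
    spacing_bp: int = 6_000_000,
    width_bp: int = 1_000_000,
) -> list[GenomicInterval]:
    """Regular multi-chromosome ACD layout used by the statistical fixtures."""
    return [
        GenomicInterval(
            chrom=f"chr{c + 1}",
            start=i * spacing_bp,
            end=i * spacing_bp + width_bp,
            id=f"ACD_chr{c + 1}_{i}",
        )
        for c in range(n_chrom)
        for i in range(n_per_chrom)
    ]


@pytest.fixture(scope="session")
def acds_multi():
    return acd_grid()


@pytest.fixture(scope="session")
def acds_one_chrom():
    return acd_grid(n_chrom=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
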