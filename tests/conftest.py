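import numpy as np
import pytest

from susiekit import generate_haplotype_panel


@pytest.fixture(scope="session")
def panel():
    """Default-condition haplotype panel (6 AR-0.9 blocks of 50 variants)."""
    return generate_haplotype_panel(seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """Small panel for fast pipeline tests."""
    return generate_haplotype_panel(
        n_haplotypes=600, n_blocks=3, block_size=20, seed=5
    )


@pytest.fixture(scope="session")
def independent_panel():
    """Panel with no LD (within-block correlation 0)."""
    return generate_haplotype_panel(
        n_haplotypes=1000, n_blocks=2, block_size=25, within_block_corr=0.0, seed=9
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_correlation(rng: np.random.Generator, p: int) -> np.ndarray:
    """Well-conditioned random correlation matrix."""
    a = rng.standard_normal((p, 2 * p + 4))
    r = np.corrcoef(a)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return r
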