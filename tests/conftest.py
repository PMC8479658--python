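import numpy as np
import pytest
import scipy.sparse as sp

from hicdci import ContactMatrix, GenomeBins, SimulationConfig


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Fast two-chromosome genome with one gained block per chromosome."""
    return SimulationConfig(
        n_chroms=2,
        bins_per_chrom=120,
        bin_size=5000,
        base_depth=100.0,
        n_replicates=2,
        blocks=[("chr1", (40, 60), 3.0), ("chr2", (70, 90), 3.0)],
        n_cres=600,
        n_trs=10,
        n_datasets_per_tr=2,
        seed=11,
    )


def make_matrix(counts: np.ndarray, chrom: str = "chr1", bin_size: int = 5000) -> ContactMatrix:
    """Wrap a dense symmetric array as a ContactMatrix on a one-chrom genome."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    bins = GenomeBins((chrom,), (n * bin_size,), bin_size)
    return ContactMatrix(chrom, bins, sp.csr_matrix(counts))


def random_symmetric_counts(rng: np.random.Generator, n: int, scale: float = 20.0) -> np.ndarray:
    m = rng.poisson(scale, size=(n, n)).astype(float)
    return np.triu(m) + np.triu(m, 1).T
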