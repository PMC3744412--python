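import numpy as np
import pytest

from bsamap.genome import Chromosome, GenomeLayout, evenly_spaced_markers
from bsamap.smoothing import SmoothBasis, fit_pool_chromosome


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def one_chrom_layout():
    """Single 1 Mb chromosome of 4 Morgans with 200 markers."""
    chrom = Chromosome("chr1", 1_000_000, 4.0)
    return evenly_spaced_markers(GenomeLayout([chrom]), 200)


def make_null_fit(seed, n_markers=150, coverage=100, pool_id="q", knots=10):
    """A fitted frequency curve from counts around p = 0.5 (no structure)."""
    r = np.random.Generator(np.random.PCG64(seed))
    pos = np.linspace(1, 1_000_000, n_markers)
    total = r.poisson(coverage, n_markers)
    v = r.binomial(total, 0.5)
    return fit_pool_chromosome(
        pos, v, total, SmoothBasis(knots=knots, grid_bp=10_000),
        pool_id=pool_id, chrom="chr1", chrom_length=1_000_000,
    )
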