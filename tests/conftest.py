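import numpy as np
import pytest

import epinipt as e
from epinipt.coverage import CoverageMatrix, SiteIndex


@pytest.fixture(scope="session")
def small_genome():
    """Default-sized genome (3 x 2 Mb, ~60k CG sites), fixed seed."""
    return e.build_genome(e.GenomeConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """Reference-design uCG cohort on the small genome."""
    cfg = e.CohortConfig(assay="uCG", depth_human_reads=5e6)
    matrix, meta, truth = e.simulate_cohort(small_genome, cfg, seed=8)
    return matrix, meta, truth


@pytest.fixture
def toy_sites():
    """Hand-built catalog: two chromosomes, a handful of well-spaced sites."""
    return SiteIndex(
        chrom_names=["chrA", "chrB"],
        chrom_lengths=np.array([1000, 500]),
        chrom_id=np.array([0, 0, 0, 0, 1, 1], dtype=np.int32),
        pos=np.array([10, 60, 100, 400, 50, 300], dtype=np.int64),
    )


def toy_matrix(counts, sites, ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    ids = ids or [f"s{i}" for i in range(counts.shape[0])]
    return CoverageMatrix(counts, ids, sites)
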