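import numpy as np
import pytest

from chromsig import synthetic_data as sd
from chromsig.io_formats import AccessibilityMatrix, GenomicRegion


def make_matrix(values, scale="raw_counts", sample_prefix="s"):
    """Small matrix helper: rows become consecutive chr1 peaks."""
    values = np.asarray(values, dtype=float)
    regions = [
        GenomicRegion("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500)
        for i in range(values.shape[0])
    ]
    samples = [f"{sample_prefix}{j + 1}" for j in range(values.shape[1])]
    return AccessibilityMatrix(regions, samples, values, scale)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (2,000 peaks, 150-peak clusters) for module tests
    that only need the planted structure, not the full study size."""
    config = sd.CohortConfig(
        n_peaks=2000, cluster_sizes=(150, 150, 150), n_chry_peaks=20, seed=7
    )
    return sd.generate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_normalized(small_cohort):
    from chromsig.normalization import normalize_pipeline

    matrix, metadata, regions, truth = small_cohort
    return normalize_pipeline(matrix), metadata, truth
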