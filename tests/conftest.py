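import numpy as np
import pytest

from smfdiag import SimConfig, build_feature_matrix, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: coarse axis, few species, everything else at defaults."""
    return SimConfig(
        n_case=12, n_control=12, n_species=40, axis_points=20000, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    spectra, labels, catalog = generate_cohort(small_config)
    return spectra, labels, catalog


@pytest.fixture(scope="session")
def small_matrix(small_cohort, small_config):
    spectra, labels, catalog = small_cohort
    matrix = build_feature_matrix(
        spectra,
        labels,
        min_separation=2 * 2.3548 * small_config.peak_sigma,
    )
    return matrix, labels, catalog


@pytest.fixture(scope="session")
def noiseless_config():
    """No noise, no jitter, no baseline: exact recovery regime."""
    return SimConfig(
        n_case=6,
        n_control=6,
        n_species=30,
        axis_points=20000,
        seed=11,
        noise_sd=0.0,
        sample_cv=0.0,
        peak_jitter_sd=0.0,
        baseline_amplitude=0.0,
    )


def marker_columns(matrix, catalog, tol=0.1):
    """Feature column index of each planted informative species."""
    cols = []
    for mz in catalog.mz_center[catalog.informative_idx]:
        j = int(np.argmin(np.abs(matrix.feature_mz - mz)))
        assert abs(matrix.feature_mz[j] - mz) <= tol
        cols.append(j)
    return np.asarray(cols)
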