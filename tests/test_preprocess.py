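import numpy as np
import pytest

from smfdiag import (
    RawSpectrum,
    SimConfig,
    align_peaks,
    build_catalog,
    build_feature_matrix,
    correct_baseline,
    cosine_qc,
    detect_peaks,
    generate_cohort,
    generate_spectrum,
    normalize,
    smooth,
)
from smfdiag.preprocess import FeatureMatrix, PeakList, filter_features


def _gauss(axis, mz0, height, sigma):
    return height * np.exp(-0.5 * ((axis - mz0) / sigma) ** 2)


# ---------------------------------------------------------------- smoothing
def test_smooth_constant_unchanged():
    s = RawSpectrum(np.linspace(100, 200, 501), np.full(501, 7.0))
    out = smooth(s, window=11, polyorder=2)
    np.testing.assert_allclose(out.intensity, 7.0, rtol=1e-10)


def test_smooth_passthrough_and_errors():
    s = RawSpectrum(np.linspace(0, 1, 50), np.random.default_rng(0).random(50))
    np.testing.assert_array_equal(smooth(s, window=1).intensity, s.intensity)
    with pytest.raises(ValueError):
        smooth(s, window=4)
    with pytest.raises(ValueError):
        smooth(s, window=3, polyorder=5)
    with pytest.raises(ValueError):
        smooth(s, window=51)


def test_smooth_reduces_noise_variance():
    rng = np.random.default_rng(1)
    s = RawSpectrum(np.linspace(100, 200, 5000), rng.random(5000))
    out = smooth(s, window=9, polyorder=2)
    assert np.var(out.intensity) < np.var(s.intensity)


# ---------------------------------------------------------------- baseline
def test_baseline_zero_input_unchanged():
    axis = np.linspace(100, 200, 4000)
    peaks = _gauss(axis, 150, 100, 0.1) + _gauss(axis, 170, 50, 0.1)
    s = RawSpectrum(axis, peaks)
    out = correct_baseline(s, half_window=50)
    np.testing.assert_allclose(out.intensity, peaks, atol=1e-9)


def test_baseline_pure_baseline_removed():
    axis = np.linspace(100, 200, 4000)
    base = 300 * np.exp(-(axis - 100) / 30)
    out = correct_baseline(RawSpectrum(axis, base), half_window=50)
    assert np.max(out.intensity) < 0.05 * 300


def test_baseline_preserves_peak_height():
    axis = np.linspace(100, 200, 8000)
    base = 200 * np.exp(-(axis - 100) / 50)
    peak = _gauss(axis, 150, 1000, 0.05)
    out = correct_baseline(RawSpectrum(axis, base + peak), half_window=60)
    i = np.argmin(np.abs(axis - 150))
    assert out.intensity[i] == pytest.approx(1000, rel=0.05)
    with pytest.raises(ValueError):
        correct_baseline(RawSpectrum(axis, base), half_window=0)


# ---------------------------------------------------------------- detection
def test_detect_flat_and_empty():
    axis = np.linspace(100, 200, 1000)
    assert len(detect_peaks(RawSpectrum(axis, np.zeros(1000)))) == 0
    assert len(detect_peaks(RawSpectrum(np.empty(0), np.empty(0)))) == 0


def test_detect_single_gaussian_center():
    axis = np.linspace(100, 200, 20000)
    rng = np.random.default_rng(2)
    noise = np.clip(rng.normal(0, 1.0, 20000), 0, None)
    s = RawSpectrum(axis, _gauss(axis, 151.234, 300, 0.05) + noise)
    pl = detect_peaks(s, snr_min=3, min_separation=0.1)
    strong = pl.mz[pl.intensity > 100]
    assert len(strong) == 1
    step = axis[1] - axis[0]
    assert abs(strong[0] - 151.234) <= step


def test_detect_merges_close_peaks_keeping_taller():
    axis = np.linspace(100, 110, 10000)
    s = RawSpectrum(
        axis, _gauss(axis, 105.0, 200, 0.02) + _gauss(axis, 105.06, 120, 0.02)
    )
    pl = detect_peaks(s, snr_min=0, min_separation=0.1)
    assert len(pl) == 1
    assert abs(pl.mz[0] - 105.0) < 0.01


def test_detect_precision_recall_high_snr():
    """At planted SNR >= 10 both precision and recall reach 0.99."""
    cfg = SimConfig(
        n_case=1, n_control=1, n_species=50, axis_points=30000, seed=21,
        noise_sd=5.0, baseline_amplitude=100.0,
    )
    cat = build_catalog(cfg)
    spec = generate_spectrum(cat, "control", seed=1)
    sm = correct_baseline(smooth(spec), 100)
    # operate at the planted-SNR threshold: noise maxima on 30k points stay below it
    pl = detect_peaks(sm, snr_min=10, min_separation=2 * 2.3548 * cfg.peak_sigma)
    d = np.min(np.abs(pl.mz[:, None] - cat.mz_center[None, :]), axis=1)
    tp = np.sum(d < 0.2)
    precision = tp / len(pl)
    dd = np.min(np.abs(cat.mz_center[:, None] - pl.mz[None, :]), axis=1)
    recall = np.sum(dd < 0.2) / len(cat)
    assert precision >= 0.99
    assert recall >= 0.99


# ---------------------------------------------------------------- alignment
def _pl(mz, inten, sid):
    return PeakList(np.asarray(mz, float), np.asarray(inten, float),
                    np.full(len(mz), 10.0), sid)


def test_align_identical_peaklists():
    pls = [_pl([100.0, 150.0, 200.0], [5, 6, 7], f"s{i}") for i in range(4)]
    m = align_peaks(pls, tolerance=0.1)
    assert m.values.shape == (4, 3)
    assert np.all(m.values > 0)
    np.testing.assert_allclose(m.feature_mz, [100.0, 150.0, 200.0])


def test_align_jitter_within_tolerance_gives_one_feature_per_species():
    rng = np.random.default_rng(3)
    centers = np.array([100.0, 150.0, 200.0, 250.0])
    pls = [
        _pl(np.sort(centers + rng.uniform(-0.03, 0.03, 4)), rng.uniform(5, 10, 4), f"s{i}")
        for i in range(6)
    ]
    m = align_peaks(pls, tolerance=0.1)
    assert m.n_features == 4


def test_align_unique_peak_zero_elsewhere():
    pls = [_pl([100.0], [5], "a"), _pl([100.0, 300.0], [5, 9], "b")]
    m = align_peaks(pls, tolerance=0.1)
    assert m.n_features == 2
    col = np.argmin(np.abs(m.feature_mz - 300.0))
    np.testing.assert_allclose(m.values[:, col], [0.0, 9.0])
    with pytest.raises(ValueError):
        align_peaks(pls, tolerance=0.0)


def test_align_permutation_equivariant():
    rng = np.random.default_rng(4)
    pls = [
        _pl(np.sort(rng.uniform(100, 200, 5)), rng.uniform(1, 10, 5), f"s{i}")
        for i in range(5)
    ]
    m1 = align_peaks(pls, tolerance=0.2)
    perm = [3, 1, 4, 0, 2]
    m2 = align_peaks([pls[i] for i in perm], tolerance=0.2)
    np.testing.assert_allclose(m2.feature_mz, m1.feature_mz)
    np.testing.assert_allclose(m2.values, m1.values[perm])


# ------------------------------------------------------------- normalization
def test_normalize_equal_sums_and_scale_invariance():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 10, (6, 8))
    m = FeatureMatrix(vals, np.sort(rng.uniform(100, 900, 8)), [f"s{i}" for i in range(6)])
    out = normalize(m, "tic")
    sums = out.values.sum(axis=1)
    np.testing.assert_allclose(sums, sums[0], rtol=1e-10)

    # doubling a raw row leaves its normalized row unchanged
    vals2 = vals.copy()
    vals2[2] *= 2
    out2 = normalize(FeatureMatrix(vals2, m.feature_mz, m.sample_ids), "tic")
    # identical up to the cohort-wide rescaling constant
    np.testing.assert_allclose(
        out2.values[2] / out2.values[2].sum(),
        out.values[2] / out.values[2].sum(),
        rtol=1e-10,
    )

    np.testing.assert_array_equal(normalize(m, "none").values, vals)


def test_normalize_zero_row_warns():
    vals = np.array([[1.0, 2.0], [0.0, 0.0]])
    m = FeatureMatrix(vals, np.array([100.0, 200.0]), ["a", "b"])
    with pytest.warns(UserWarning, match="all-zero"):
        out = normalize(m, "tic")
    np.testing.assert_array_equal(out.values[1], 0.0)


# ---------------------------------------------------------------------- QC
def test_cosine_identical_rows_score_one():
    vals = np.tile([1.0, 2.0, 3.0], (4, 1))
    m = FeatureMatrix(vals, np.array([1.0, 2.0, 3.0]), list("abcd"))
    scores = cosine_qc(m, ["g1", "g1", "g2", "g2"])
    np.testing.assert_allclose(scores, 1.0)


def test_cosine_orthogonal_rows_score_zero():
    m = FeatureMatrix(np.eye(2), np.array([1.0, 2.0]), ["a", "b"])
    np.testing.assert_allclose(cosine_qc(m, ["g", "g"]), 0.0)


def test_cosine_scale_invariance(small_matrix):
    matrix, labels, _ = small_matrix
    s1 = cosine_qc(matrix, labels)
    scaled = FeatureMatrix(
        matrix.values * np.random.default_rng(6).uniform(0.5, 2.0, (matrix.n_samples, 1)),
        matrix.feature_mz, matrix.sample_ids,
    )
    np.testing.assert_allclose(cosine_qc(scaled, labels), s1, rtol=1e-10)


def test_cosine_zero_row_warns_and_group_size_guard():
    m = FeatureMatrix(np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]),
                      np.array([1.0, 2.0]), list("abc"))
    with pytest.warns(UserWarning, match="zero-norm"):
        scores = cosine_qc(m, ["g", "g", "g"])
    assert scores[1] == 0.0
    with pytest.raises(ValueError, match="fewer than 2"):
        cosine_qc(m, ["g", "g", "h"])


# ------------------------------------------------------------- end to end
def test_noiseless_end_to_end_recovery(noiseless_config):
    """Noiseless cohort: feature count equals the species count and matrix
    values correlate > 0.999 with the planted per-sample peak heights."""
    spectra, labels, cat = generate_cohort(noiseless_config)
    m = build_feature_matrix(
        spectra, labels, norm_method="none",
        min_separation=2 * 2.3548 * noiseless_config.peak_sigma,
    )
    assert m.n_features == len(cat)
    axis = noiseless_config.mz_axis
    truth = np.empty_like(m.values)
    for j, mz in enumerate(cat.mz_center):
        i = np.argmin(np.abs(axis - mz))
        truth[:, j] = [s.intensity[i] for s in spectra]
    r = np.corrcoef(truth.ravel(), m.values.ravel())[0, 1]
    assert r > 0.999


def test_default_cohort_qc_regime(small_matrix):
    matrix, labels, _ = small_matrix
    scores = cosine_qc(matrix, labels)
    assert np.mean(scores > 0.9) >= 0.9


def test_filter_features_prevalence():
    vals = np.array([[1.0, 0.0, 2.0], [1.0, 0.0, 0.0], [1.0, 3.0, 0.0], [1.0, 0.0, 0.0]])
    m = FeatureMatrix(vals, np.array([1.0, 2.0, 3.0]), list("abcd"))
    out = filter_features(m, min_fraction=0.5)
    np.testing.assert_array_equal(out.feature_mz, [1.0])
    out_all = filter_features(m, min_fraction=0.0)
    assert out_all.n_features == 3
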