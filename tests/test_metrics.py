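import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfdiag.metrics import (
    bootstrap_ci,
    compare_auc,
    diagnostic_report,
    fold_changes,
    pca_scores,
    power_curve,
    propensity_match,
    roc_auc,
    youden_point,
)

from tests.oracles import brute_force_auc, normal_power_two_sample


# --------------------------------------------------------------------- AUC
def test_auc_worked_example():
    auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert auc == pytest.approx(0.75)


def test_auc_edge_cases():
    assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])[0] == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1])[0] == 0.5
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


@pytest.mark.parametrize("seed", range(10))
def test_auc_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 51))
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    labels = rng.integers(0, 2, n)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_monotone_invariance_and_complement(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    scores = rng.random(n)
    labels = rng.integers(0, 2, n)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    auc, _ = roc_auc(scores, labels)
    # strictly monotone transform leaves the rank-based AUC unchanged
    auc_t, _ = roc_auc(np.exp(3 * scores) + 1, labels)
    assert auc_t == pytest.approx(auc, abs=1e-12)
    auc_c, _ = roc_auc(scores, 1 - labels)
    assert auc_c == pytest.approx(1 - auc, abs=1e-12)


# ---------------------------------------------------------------- bootstrap
def test_bootstrap_ci_basic_properties():
    rng = np.random.default_rng(0)
    scores = np.r_[rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)]
    labels = np.r_[np.zeros(60), np.ones(60)]
    lo, hi = bootstrap_ci(scores, labels, B=500, seed=1)
    auc, _ = roc_auc(scores, labels)
    assert lo <= auc <= hi
    assert (lo, hi) == bootstrap_ci(scores, labels, B=500, seed=1)
    with pytest.raises(ValueError):
        bootstrap_ci(scores, labels, B=10)


def test_bootstrap_ci_perfect_separation_upper_is_one():
    scores = np.r_[np.zeros(50), np.ones(50)]
    labels = scores.astype(int)
    lo, hi = bootstrap_ci(scores, labels, B=200, seed=0)
    assert hi == 1.0


def test_bootstrap_ci_width_at_study_scale():
    """Two-Gaussian scores with analytic AUC 0.95 at n=731: the 95% CI is
    narrower than 0.05, the regime reported for discovery-scale cohorts."""
    from scipy.stats import norm

    delta = np.sqrt(2) * norm.ppf(0.95)
    rng = np.random.default_rng(4)
    scores = np.r_[rng.normal(0, 1, 374), rng.normal(delta, 1, 357)]
    labels = np.r_[np.zeros(374), np.ones(357)]
    lo, hi = bootstrap_ci(scores, labels, B=1000, seed=2)
    assert hi - lo < 0.05


# ------------------------------------------------------------------- Youden
def test_youden_perfect_separation():
    _, curve = roc_auc([0, 0.1, 0.9, 1.0], [0, 0, 1, 1])
    thr, sens, spec = youden_point(curve)
    assert sens == 1.0 and spec == 1.0


def test_youden_symmetric_gaussians_threshold_midpoint():
    rng = np.random.default_rng(5)
    a, b = 0.0, 2.0
    scores = np.r_[rng.normal(a, 1, 4000), rng.normal(b, 1, 4000)]
    labels = np.r_[np.zeros(4000), np.ones(4000)]
    _, curve = roc_auc(scores, labels)
    thr, _, _ = youden_point(curve)
    # closed form: equal-variance symmetric case crosses at the midpoint
    assert thr == pytest.approx((a + b) / 2, abs=0.15)


def test_youden_single_positive():
    _, curve = roc_auc([0.2, 0.4, 0.9], [0, 0, 1])
    _, sens, _ = youden_point(curve)
    assert sens in (0.0, 1.0)


# ------------------------------------------------------------- compare_auc
def test_compare_auc_identical_scores():
    rng = np.random.default_rng(6)
    s = rng.random(80)
    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    p = compare_auc(s, s, y, B=300, seed=0)
    assert p > 0.9


def test_compare_auc_strong_vs_null_and_symmetry():
    rng = np.random.default_rng(7)
    y = np.r_[np.zeros(350), np.ones(350)]
    strong = y + rng.normal(0, 0.5, 700)
    null = rng.random(700)
    p = compare_auc(strong, null, y, B=300, seed=1)
    assert p < 0.05
    p_swap = compare_auc(null, strong, y, B=300, seed=1)
    assert p_swap == pytest.approx(p, abs=1e-12)


# ------------------------------------------------------------ fold changes
def test_fold_changes_exact_cases():
    X = np.tile([2.0, 4.0], (10, 1))
    y = np.r_[np.ones(5), np.zeros(5)]
    np.testing.assert_allclose(fold_changes(X, y, [0, 1]), 1.0)

    X2 = X.copy()
    X2[y == 1] *= 2
    np.testing.assert_allclose(fold_changes(X2, y, [0, 1]), 2.0)

    X3 = np.zeros((10, 1))
    X3[y == 1] = 1.0
    with pytest.warns(UserWarning, match="undefined"):
        fc = fold_changes(X3, y, [0])
    assert np.isnan(fc[0])


def test_fold_change_recovery_at_study_scale():
    """Planted fold change 1.5 with log-normal per-sample jitter at
    357/374 estimates within [1.4, 1.6]."""
    rng = np.random.default_rng(8)
    tau = 0.3
    ctrl = np.exp(rng.normal(0, tau, (374, 1)))
    case = 1.5 * np.exp(rng.normal(0, tau, (357, 1)))
    X = np.vstack([case, ctrl])
    y = np.r_[np.ones(357), np.zeros(374)]
    fc = fold_changes(X, y, [0])[0]
    assert 1.4 <= fc <= 1.6


# -------------------------------------------------------------------- PCA
def test_pca_line_and_duplicates():
    t = np.linspace(0, 1, 30)[:, None]
    X = np.hstack([t, 2 * t, -t]) + 1e-9 * np.random.default_rng(9).standard_normal((30, 3))
    scores, evr = pca_scores(X)
    assert evr[0] > 0.999
    assert np.all(np.diff(evr) <= 1e-12)

    Xd = np.vstack([X, X])
    sd, _ = pca_scores(Xd)
    np.testing.assert_allclose(sd[:30], sd[30:], atol=1e-8)


def test_pca_separates_planted_clusters():
    rng = np.random.default_rng(10)
    a = rng.normal(0, 1, (100, 5))
    b = rng.normal(0, 1, (100, 5)) + [6, 0, 0, 0, 0]
    X = np.vstack([a, b])
    scores, _ = pca_scores(X)
    pc1 = scores[:, 0]
    thr = np.median(pc1)
    pred = pc1 > thr
    truth = np.r_[np.zeros(100), np.ones(100)].astype(bool)
    acc = max(np.mean(pred == truth), np.mean(pred == ~truth))
    assert acc >= 0.95


# -------------------------------------------------------------------- power
def test_power_null_effect_equals_alpha():
    closed, mc = power_curve([0.0], [64], alpha=0.05, n_mc=20000, seed=0)
    assert closed[0, 0] == pytest.approx(0.05, abs=1e-6)
    assert mc[0, 0] == pytest.approx(0.05, abs=0.01)


def test_power_benchmark_point_and_monotonicity():
    closed, mc = power_curve([0.5], [32, 64, 128], alpha=0.05, n_mc=30000, seed=1)
    assert closed[0, 1] == pytest.approx(normal_power_two_sample(0.5, 64), abs=1e-12)
    assert closed[0, 1] == pytest.approx(0.80, abs=0.02)
    assert abs(mc[0, 1] - closed[0, 1]) < 0.02
    assert np.all(np.diff(closed[0]) > 0)
    assert np.all(np.diff(mc[0]) > 0)


def test_power_closed_form_against_statsmodels():
    sm_power = pytest.importorskip("statsmodels.stats.power")
    closed, _ = power_curve([0.5], [64], n_mc=100, seed=0)
    ref = sm_power.NormalIndPower().power(0.5, nobs1=64, alpha=0.05, ratio=1.0)
    assert closed[0, 0] == pytest.approx(ref, abs=1e-6)


# ---------------------------------------------------------------- matching
def test_propensity_match_balanced_all_matched():
    rng = np.random.default_rng(11)
    cov = rng.normal(0, 1, (100, 2))
    group = np.r_[np.ones(50), np.zeros(50)]
    # identical covariate distributions: with an unrestrictive caliper every
    # treated unit finds a control
    pairs, unmatched = propensity_match(cov, group, caliper_sd=5.0, seed=0)
    assert len(pairs) == 50
    assert unmatched == []
    # matched without replacement
    controls = [c for _, c in pairs]
    assert len(set(controls)) == len(controls)


def test_propensity_match_disjoint_supports_no_matches():
    cov = np.r_[np.zeros(20), np.ones(20) * 10][:, None]
    group = np.r_[np.ones(20), np.zeros(20)]
    pairs, unmatched = propensity_match(cov, group, caliper_sd=0.01, seed=0)
    assert pairs == []
    assert len(unmatched) == 20


def test_propensity_match_reduces_confounding():
    """Confounded cohort: post-matching standardized mean differences < 0.1."""
    rng = np.random.default_rng(12)
    n = 400
    age = rng.normal(50, 10, n)
    sex = rng.integers(0, 2, n).astype(float)
    logit = -8.0 + 0.15 * age + 0.5 * sex
    treated = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    if treated.sum() < 20:
        treated[:20] = 1
    cov = np.c_[age, sex]
    pairs, _ = propensity_match(cov, treated, seed=1)
    ti = [a for a, _ in pairs]
    ci = [b for _, b in pairs]
    for j in range(2):
        diff = cov[ti, j].mean() - cov[ci, j].mean()
        pooled = np.sqrt(0.5 * (cov[ti, j].var() + cov[ci, j].var()))
        assert abs(diff) / pooled < 0.1


# ------------------------------------------------------------------ report
def test_diagnostic_report_consistency():
    rng = np.random.default_rng(13)
    scores = np.r_[rng.normal(0, 1, 80), rng.normal(2, 1, 80)]
    labels = np.r_[np.zeros(80), np.ones(80)]
    rep = diagnostic_report(scores, labels, B=200, seed=0)
    assert rep.ci_low <= rep.auc <= rep.ci_high
    assert rep.n_case == 80 and rep.n_control == 80
    # sensitivity/specificity recomputable from stored threshold + scores
    calls = scores >= rep.threshold
    assert rep.sensitivity == pytest.approx(calls[labels == 1].mean())
    assert rep.specificity == pytest.approx((~calls)[labels == 0].mean())
    assert "AUC" in rep.summary()
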