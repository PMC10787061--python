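"""Diagnostic read-out statistics.

ROC/AUC (rank-based, midrank ties), stratified percentile-bootstrap CIs,
Youden operating points, paired-bootstrap AUC comparison, fold changes, PCA
score plots, two-sample power curves (closed form + Monte Carlo), and 1:1
propensity-score matching with a caliper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, ttest_ind
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

__all__ = [
    "DiagnosticReport",
    "roc_auc",
    "bootstrap_ci",
    "youden_point",
    "compare_auc",
    "fold_changes",
    "pca_scores",
    "power_curve",
    "propensity_match",
    "diagnostic_report",
]


def _to_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    return (y == classes[-1]).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence):
    """Rank-based AUC (= Mann-Whitney probability, midrank ties) + ROC curve.

    Returns ``(auc, (fpr, tpr, thresholds))``.
    """
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return auc, (fpr, tpr, thr)


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
):
    """Stratified percentile-bootstrap CI for the AUC.

    Cases and controls are resampled separately so every replicate keeps both
    classes; replicates that still degenerate (all-tied scores in a class are
    fine; a missing class cannot occur) are never produced.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    case, ctrl = s[y == 1], s[y == 0]
    n1, n0 = len(case), len(ctrl)
    boots = np.empty(B)
    for b in range(B):
        cs = case[rng.integers(0, n1, n1)]
        ct = ctrl[rng.integers(0, n0, n0)]
        yy = np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]
        boots[b] = roc_auc_score(yy, np.r_[cs, ct])
    lo_q = (1 - level) / 2
    lo, hi = np.quantile(boots, [lo_q, 1 - lo_q])
    return float(lo), float(hi)


def youden_point(roc: tuple):
    """Operating point maximizing sensitivity + specificity - 1.

    ``roc`` is the (fpr, tpr, thresholds) triple from :func:`roc_auc`.
    Ties take the lowest threshold (favoring sensitivity). Returns
    ``(threshold, sensitivity, specificity)``.
    """
    fpr, tpr, thr = roc
    j = tpr - fpr
    best = np.max(j)
    # candidates tied on J: lowest threshold = last index (thresholds descend)
    idx = np.flatnonzero(j >= best - 1e-12)[-1]
    return float(thr[idx]), float(tpr[idx]), float(1 - fpr[idx])


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    B: int = 2000,
    seed: int = 0,
) -> float:
    """Paired-bootstrap two-sided p-value for AUC(a) != AUC(b).

    Samples are resampled jointly (stratified by class) so the two AUCs stay
    paired; p is the symmetric tail probability of the null-centered
    bootstrap distribution of the AUC difference.
    """
    y = _to_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b, labels must share length")
    rng = np.random.default_rng(seed)
    i1, i0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    d_obs = roc_auc_score(y, a) - roc_auc_score(y, b)
    diffs = np.empty(B)
    for k in range(B):
        idx = np.r_[i1[rng.integers(0, len(i1), len(i1))],
                    i0[rng.integers(0, len(i0), len(i0))]]
        yy = y[idx]
        diffs[k] = roc_auc_score(yy, a[idx]) - roc_auc_score(yy, b[idx])
    # center at the observed difference; two-sided tail of 0 under that law
    p = 2 * min(np.mean(diffs - d_obs <= -abs(d_obs)) + 1 / (B + 1),
                np.mean(diffs - d_obs >= abs(d_obs)) + 1 / (B + 1))
    return float(min(p, 1.0))


def fold_changes(X: np.ndarray, labels: Sequence, features: Sequence[int]) -> np.ndarray:
    """mean(case)/mean(control) per feature on the intensity (not log) scale.

    Zero control means give NaN (undefined) with a warning; callers should
    exclude those from summaries.
    """
    y = _to_binary(labels)
    X = np.asarray(X, dtype=float)
    feats = np.asarray(features, dtype=int)
    case = X[y == 1][:, feats].mean(axis=0)
    ctrl = X[y == 0][:, feats].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = case / ctrl
    if np.any(ctrl == 0):
        warnings.warn("zero control mean: fold change undefined (NaN) for some features")
        fc[ctrl == 0] = np.nan
    return fc


def pca_scores(X: np.ndarray, n_components: int = 2):
    """PCA scores of column-centered data + explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    pca = PCA(n_components=min(n_components, X.shape[0] - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def power_curve(
    effect_sizes: Sequence[float],
    n_per_group: Sequence[int],
    alpha: float = 0.05,
    n_mc: int = 20_000,
    seed: int = 0,
):
    """Two-sample two-sided test power over an (effect, n) grid.

    Closed form is the normal approximation
    ``Phi(d*sqrt(n/2) - z_{1-a/2}) + Phi(-d*sqrt(n/2) - z_{1-a/2})``; the
    Monte-Carlo arm simulates Welch t-tests on normal samples. Returns two
    arrays of shape (len(effect_sizes), len(n_per_group)): (closed, mc).
    """
    effects = np.asarray(effect_sizes, dtype=float)
    ns = np.asarray(n_per_group, dtype=int)
    if np.any(effects < 0) or np.any(ns < 2):
        raise ValueError("effect sizes must be >= 0 and n >= 2 per group")
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(2.0 / ns)[None, :]
    shift = effects[:, None] / se
    closed = norm.cdf(shift - z) + norm.cdf(-shift - z)

    rng = np.random.default_rng(seed)
    mc = np.empty_like(closed)
    for i, d in enumerate(effects):
        for j, n in enumerate(ns):
            a = rng.standard_normal((n_mc, n)) + d
            b = rng.standard_normal((n_mc, n))
            _, p = ttest_ind(a, b, axis=1)
            mc[i, j] = np.mean(p < alpha)
    return closed, mc


def propensity_match(
    covariates: np.ndarray,
    group: Sequence,
    ratio: int = 1,
    caliper_sd: float = 0.2,
    seed: int = 0,
):
    """Greedy nearest-neighbour 1:ratio matching on the propensity logit.

    The propensity is a logistic regression of group on the (numeric-encoded)
    covariates; matching is without replacement on the logit scale with a
    caliper of ``caliper_sd`` times the pooled logit sd. Treated units are
    processed in seeded random order. Returns ``(pairs, unmatched_treated)``
    where pairs is a list of (treated_index, control_index).
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = _to_binary(group)
    if t.sum() == 0 or (1 - t).sum() == 0:
        raise ValueError("both groups must be non-empty")
    lr = LogisticRegression(max_iter=2000)
    lr.fit(X, t)
    p = np.clip(lr.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    caliper = caliper_sd * float(np.std(logit))

    treated = np.flatnonzero(t == 1)
    controls = np.flatnonzero(t == 0)
    if len(controls) < len(treated) * ratio:
        warnings.warn("fewer controls than treated x ratio: matching will be partial")
    rng = np.random.default_rng(seed)
    order = rng.permutation(treated)
    available = dict.fromkeys(controls.tolist())
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for ti in order:
        got = 0
        for _ in range(ratio):
            if not available:
                break
            avail = np.fromiter(available.keys(), dtype=int)
            d = np.abs(logit[avail] - logit[ti])
            j = int(np.argmin(d))
            if d[j] <= caliper:
                ci = int(avail[j])
                pairs.append((int(ti), ci))
                del available[ci]
                got += 1
            else:
                break
        if got < ratio:
            unmatched.append(int(ti))
    return pairs, unmatched


@dataclass
class DiagnosticReport:
    """AUC + CI, Youden operating point, and per-sample calls."""

    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    probabilities: np.ndarray
    calls: np.ndarray

    def to_json(self) -> str:
        d = asdict(self)
        d["probabilities"] = [float(p) for p in self.probabilities]
        d["calls"] = [int(c) for c in self.calls]
        return json.dumps(d)

    def summary(self) -> str:
        return (
            f"AUC {self.auc:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}); "
            f"sens/spec {100 * self.sensitivity:.1f}%/{100 * self.specificity:.1f}% "
            f"at threshold {self.threshold:.3f} "
            f"(n = {self.n_case} case / {self.n_control} control)"
        )


def diagnostic_report(
    scores: Sequence[float],
    labels: Sequence,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    threshold: Optional[float] = None,
) -> DiagnosticReport:
    """Bundle AUC, bootstrap CI and the Youden (or supplied) operating point."""
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc, curve = roc_auc(s, y)
    lo, hi = bootstrap_ci(s, y, B=B, level=level, seed=seed)
    if threshold is None:
        threshold, sens, spec = youden_point(curve)
    else:
        calls_t = s >= threshold
        sens = float(calls_t[y == 1].mean())
        spec = float((~calls_t)[y == 0].mean())
    calls = (s >= threshold).astype(int)
    return DiagnosticReport(
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        threshold=float(threshold),
        sensitivity=float(sens),
        specificity=float(spec),
        n_case=int(y.sum()),
        n_control=int((1 - y).sum()),
        probabilities=s,
        calls=calls,
    )
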