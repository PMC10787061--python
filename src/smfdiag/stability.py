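"""Stability feature selection and biomarker-panel construction.

The feature funnel: the full fingerprint (~900 features) -> the stable set
(features selected with nonzero weight in >= freq_min of the 100 CV models
AND univariately significant) -> the top-k panel, refit as a standalone
diagnostic with its own re-tuned penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from .metrics import DiagnosticReport, bootstrap_ci, diagnostic_report, fold_changes
from .sparse import (
    ModelEnsemble,
    SparseModel,
    _validate_xy,
    fit_sparse,
    predict_proba,
    train_ensemble,
    tune_penalty,
)

__all__ = [
    "StabilityProfile",
    "BiomarkerPanel",
    "stability_profile",
    "select_stable",
    "build_panel",
    "evaluate_panel",
]


@dataclass
class StabilityProfile:
    """Per-feature ensemble-selection summary.

    selection_frequency counts the ensemble models (0..len(ensemble)) with a
    nonzero weight on the feature; mean_abs_weight averages |weight| over the
    models where it was selected; p_value is the two-sided Mann-Whitney U test
    of case vs control intensities; fold_change is mean(case)/mean(control).
    """

    feature_mz: np.ndarray
    selection_frequency: np.ndarray
    mean_abs_weight: np.ndarray
    p_value: np.ndarray
    fold_change: np.ndarray
    ensemble_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_mz": np.round(self.feature_mz, 4),
                "selection_frequency": self.selection_frequency,
                "mean_abs_weight": self.mean_abs_weight,
                "p_value": self.p_value,
                "fold_change": self.fold_change,
            }
        )


@dataclass
class BiomarkerPanel:
    """A small fixed feature set refit as its own sparse diagnostic."""

    feature_idx: np.ndarray
    feature_mz: np.ndarray
    model: SparseModel
    k: int
    labels: Optional[list[str]] = None  # optional metabolite display names

    def to_json(self) -> str:
        d = {
            "k": int(self.k),
            "feature_idx": [int(i) for i in self.feature_idx],
            "feature_mz": [round(float(m), 4) for m in self.feature_mz],
            "model": self.model.to_dict(self.feature_mz),
        }
        if self.labels is not None:
            d["metabolite_labels"] = list(self.labels)
        return json.dumps(d)


def stability_profile(
    ensemble: ModelEnsemble,
    X: np.ndarray,
    y: Sequence,
    feature_mz=None,
    intensity_values: Optional[np.ndarray] = None,
) -> StabilityProfile:
    """Summarize an ensemble into per-feature frequency, weight, p, fold change.

    ``X`` is the matrix the models were fitted on (typically log1p of the
    normalized intensities); fold changes are conventionally reported on the
    intensity scale, so pass the un-logged matrix as ``intensity_values``
    (defaults to ``X``). Pure function of its inputs: recomputation
    reproduces it exactly.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if any(len(m.weights) != p for m in ensemble.models):
        raise ValueError("ensemble and matrix feature counts differ")
    _, y01 = _validate_xy(X, y)
    case, ctrl = X[y01 == 1], X[y01 == 0]

    freq = np.zeros(p, dtype=int)
    wsum = np.zeros(p)
    for m in ensemble.models:
        nz = m.nonzero_features
        freq[nz] += 1
        wsum[nz] += np.abs(m.weights[nz])
    mean_abs = np.where(freq > 0, wsum / np.maximum(freq, 1), 0.0)

    pvals = np.ones(p)
    for j in range(p):
        if np.all(case[:, j] == case[0, j]) and np.all(ctrl[:, j] == case[0, j]):
            pvals[j] = 1.0  # constant feature, no evidence either way
        else:
            pvals[j] = mannwhitneyu(case[:, j], ctrl[:, j], alternative="two-sided").pvalue

    fc_src = X if intensity_values is None else np.asarray(intensity_values, dtype=float)
    if fc_src.shape != X.shape:
        raise ValueError("intensity_values shape must match X")
    fc = fold_changes(fc_src, y01, np.arange(p))
    if feature_mz is None:
        feature_mz = np.arange(p, dtype=float)
    return StabilityProfile(
        feature_mz=np.asarray(feature_mz, dtype=float),
        selection_frequency=freq,
        mean_abs_weight=mean_abs,
        p_value=pvals,
        fold_change=fc,
        ensemble_size=len(ensemble),
    )


def select_stable(
    profile: StabilityProfile, freq_min: int = 95, alpha: float = 0.05
) -> np.ndarray:
    """Indices of features with frequency >= freq_min and p < alpha.

    Ordered by selection frequency then mean absolute weight (both
    descending), ties broken by ascending m/z — a total, deterministic order.
    """
    if not 0 <= freq_min <= profile.ensemble_size:
        raise ValueError("freq_min outside [0, ensemble size]")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha outside [0, 1]")
    mask = (profile.selection_frequency >= freq_min) & (profile.p_value < alpha)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        warnings.warn("no features pass the stability thresholds")
        return idx
    order = sorted(
        idx,
        key=lambda j: (
            -profile.selection_frequency[j],
            -profile.mean_abs_weight[j],
            profile.feature_mz[j],
        ),
    )
    return np.asarray(order, dtype=int)


def build_panel(
    X: np.ndarray,
    y: Sequence,
    stable_set: Sequence[int],
    k: int = 4,
    seed: int = 0,
    feature_mz=None,
    metabolite_labels: Optional[Sequence[str]] = None,
) -> BiomarkerPanel:
    """Top-k stable features, refit as a standalone sparse model.

    The penalty is re-tuned on the k-column matrix (a truncated full-profile
    model would miscalibrate the intercept), so the panel is its own
    diagnostic.
    """
    stable_set = np.asarray(stable_set, dtype=int)
    if k > len(stable_set):
        raise ValueError(f"k={k} exceeds stable set size {len(stable_set)}")
    idx = stable_set[:k]
    Xk = np.asarray(X, dtype=float)[:, idx]
    lam, _ = tune_penalty(Xk, y, rounds=2, folds=5, seed=seed)
    model = fit_sparse(Xk, y, lam)
    mz = (
        np.asarray(feature_mz, dtype=float)[idx]
        if feature_mz is not None
        else idx.astype(float)
    )
    return BiomarkerPanel(
        feature_idx=idx,
        feature_mz=mz,
        model=model,
        k=k,
        labels=list(metabolite_labels) if metabolite_labels is not None else None,
    )


def evaluate_panel(
    panel: BiomarkerPanel,
    X: np.ndarray,
    y: Sequence,
    X_external=None,
    y_external=None,
    rounds: int = 20,
    folds: int = 5,
    seed: int = 0,
    bootstrap: int = 2000,
):
    """Discovery-style (cross-validated) and validation-style panel read-outs.

    Discovery: a rounds x folds CV ensemble on the panel columns, reported via
    pooled out-of-fold probabilities. Validation: the panel's fixed model
    applied to the external cohort without refitting. Also reports each
    marker's single-feature AUC (sign-corrected, since a marker may be down-
    regulated). Returns ``(discovery_report, validation_report_or_None,
    single_marker_aucs)``.
    """
    X = np.asarray(X, dtype=float)
    _, y01 = _validate_xy(X, y)
    Xk = X[:, panel.feature_idx]

    ens = train_ensemble(Xk, y01, panel.model.penalty, rounds, folds, seed=seed)
    oof = np.zeros(len(y01))
    counts = np.zeros(len(y01))
    for m, ((r, f), val) in zip(ens.models, sorted(ens.fold_plan.items())):
        oof[val] += predict_proba(m, Xk[val])
        counts[val] += 1
    oof /= counts
    disc = diagnostic_report(oof, y01, B=bootstrap, seed=seed)

    ext = None
    if X_external is not None:
        Xe = np.asarray(X_external, dtype=float)[:, panel.feature_idx]
        _, ye = _validate_xy(Xe, y_external)
        ext = diagnostic_report(predict_proba(panel.model, Xe), ye, B=bootstrap, seed=seed)

    single = {}
    for i, (j, mz) in enumerate(zip(panel.feature_idx, panel.feature_mz)):
        a = roc_auc_score(y01, X[:, j])
        single[f"{mz:.4f}"] = float(max(a, 1 - a))
    return disc, ext, single
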