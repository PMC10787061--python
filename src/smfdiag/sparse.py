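"""Sparse learning of serum metabolic fingerprints.

The diagnostic core is L1-regularized logistic regression

    min_{w,b}  (1/n) sum_i log(1 + exp(-s_i (w.x_i + b))) + lam * ||w||_1

(s_i = +/-1), solved by FISTA (accelerated proximal gradient) with the
soft-threshold prox on w and an unpenalized intercept. Features are
standardized internally on the training data; returned weights are mapped back
to the original feature scale. The estimator is wrapped in an ensemble of
``rounds`` repeats of stratified ``folds``-fold cross-validation (default
20 x 5 = 100 models), each model scored by ROC AUC on its held-out fold; the
"optimized model" is the ensemble member with the best validation AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SparseModel",
    "ModelEnsemble",
    "fit_sparse",
    "predict_proba",
    "lambda_max",
    "default_lambda_grid",
    "tune_penalty",
    "train_ensemble",
    "select_optimized_model",
    "reference_classifiers",
]

_ZERO_TOL = 1e-10


@dataclass
class SparseModel:
    """A fitted L1-logistic model in original feature scale."""

    weights: np.ndarray
    intercept: float
    penalty: float
    # standardized-scale copies, kept for exact-zero bookkeeping and warm starts
    weights_std: np.ndarray = field(default=None, repr=False)
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)

    @property
    def nonzero_features(self) -> np.ndarray:
        w = self.weights_std if self.weights_std is not None else self.weights
        return np.flatnonzero(np.abs(w) > _ZERO_TOL)

    @property
    def n_nonzero(self) -> int:
        return len(self.nonzero_features)

    def to_dict(self, feature_mz: Optional[Sequence[float]] = None) -> dict:
        d = {
            "intercept": float(self.intercept),
            "penalty": float(self.penalty),
        }
        if feature_mz is not None:
            d["weights"] = {
                f"{m:.4f}": float(w) for m, w in zip(feature_mz, self.weights)
            }
        else:
            d["weights"] = [float(w) for w in self.weights]
        return d


def _validate_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes!r}")
    ybin = (y == classes[-1]).astype(float)
    if ybin.sum() < 2 or (1 - ybin).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    return X, ybin


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log1pexp(z: np.ndarray) -> np.ndarray:
    # log(1 + e^z), overflow-safe
    out = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
    return out


def l1_logistic_objective(
    X: np.ndarray, y01: np.ndarray, w: np.ndarray, b: float, lam: float
) -> float:
    """Mean logistic deviance + lam * ||w||_1 (y01 in {0,1})."""
    z = X @ w + b
    # -y*z + log(1+e^z) is the negative log-likelihood for y in {0,1}
    nll = float(np.mean(_log1pexp(z) - y01 * z))
    return nll + lam * float(np.abs(w).sum())


def fit_sparse(
    X: np.ndarray,
    y: Sequence,
    lam: float,
    *,
    max_iter: int = 2000,
    tol: float = 1e-9,
    warm_start: Optional[SparseModel] = None,
) -> SparseModel:
    """Fit the L1-logistic model by FISTA on internally standardized features.

    Deterministic for fixed inputs. ``warm_start`` (a model fitted on the same
    training rows, e.g. at a neighbouring penalty) speeds up path fits.
    """
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    X, y01 = _validate_xy(X, y)
    n, p = X.shape
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    # Lipschitz constant of the smooth part: ||A||_2^2 / (4n), A = [Xs, 1]
    A_norm2 = _top_sv_sq(Xs, n)
    L = (A_norm2) / (4.0 * n)
    step = 1.0 / L

    if warm_start is not None and warm_start.weights_std is not None:
        # valid when the warm model was fitted on the same training rows
        w = warm_start.weights_std.copy()
        b = warm_start.intercept + float(warm_start.weights @ mean)
    else:
        w = np.zeros(p)
        b = 0.0

    wv, bv = w.copy(), b  # FISTA extrapolation point
    t = 1.0
    obj_prev = l1_logistic_objective(Xs, y01, w, b, lam)
    for _ in range(max_iter):
        z = Xs @ wv + bv
        r = _sigmoid(z) - y01
        grad_w = Xs.T @ r / n
        grad_b = float(r.mean())
        w_new = _soft_threshold(wv - step * grad_w, step * lam)
        b_new = bv - step * grad_b
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_new
        wv = w_new + beta * (w_new - w)
        bv = b_new + beta * (b_new - b)
        w, b, t = w_new, b_new, t_new
        obj = l1_logistic_objective(Xs, y01, w, b, lam)
        if obj > obj_prev:  # restart acceleration on non-monotone step
            wv, bv, t = w.copy(), b, 1.0
        if abs(obj_prev - obj) <= tol * max(1.0, abs(obj_prev)):
            break
        obj_prev = obj

    w[np.abs(w) <= _ZERO_TOL] = 0.0
    w_orig = w / scale
    b_orig = b - float(w_orig @ mean)
    model = SparseModel(
        weights=w_orig,
        intercept=b_orig,
        penalty=lam,
        weights_std=w,
        mean_=mean,
        scale_=scale,
    )
    return model


def _top_sv_sq(Xs: np.ndarray, n: int, iters: int = 50) -> float:
    """Squared top singular value of [Xs, 1] by power iteration (deterministic)."""
    p = Xs.shape[1]
    v = np.full(p + 1, 1.0 / np.sqrt(p + 1))
    s = 1.0
    for _ in range(iters):
        u = Xs @ v[:-1] + v[-1]
        v_new = np.concatenate([Xs.T @ u, [u.sum()]])
        s = float(np.linalg.norm(v_new))
        if s == 0:
            return float(n)
        v = v_new / s
    return s


def _soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def predict_proba(model: SparseModel, X: np.ndarray) -> np.ndarray:
    """P(case) per sample: logistic transform of the linear score."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature count mismatch: model has {len(model.weights)}, X has "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    return _sigmoid(X @ model.weights + model.intercept)


def lambda_max(X: np.ndarray, y: Sequence) -> float:
    """Smallest penalty that zeroes every weight: max |Xs'(y - ybar)| / n."""
    X, y01 = _validate_xy(X, y)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    return float(np.max(np.abs(Xs.T @ (y01 - y01.mean()))) / len(y01))


def default_lambda_grid(X: np.ndarray, y: Sequence, num: int = 10, decades: float = 3.0):
    """Log-spaced grid from lambda_max down, ascending order."""
    lmax = lambda_max(X, y)
    return np.geomspace(lmax * 10 ** (-decades), lmax, num)


def _stratified_plan(y01: np.ndarray, rounds: int, folds: int, seed: int):
    """(round, fold) -> validation index arrays, seeded per round.

    Folds are stratified whenever the smallest class allows it; beyond that
    (e.g. leave-one-out, folds = n) plain shuffled folds are used and
    single-class validation folds get a NaN AUC downstream.
    """
    counts = np.bincount(y01.astype(int))
    if folds > len(y01):
        raise ValueError(f"{folds}-fold CV needs at least {folds} samples")
    plan = {}
    for r in range(rounds):
        cls = StratifiedKFold if counts.min() >= folds else KFold
        kf = cls(n_splits=folds, shuffle=True, random_state=seed + 1000 * r)
        for f, (_, val) in enumerate(kf.split(np.zeros(len(y01)), y01)):
            plan[(r, f)] = val
    return plan


def tune_penalty(
    X: np.ndarray,
    y: Sequence,
    lam_grid: Optional[Sequence[float]] = None,
    rounds: int = 2,
    folds: int = 5,
    seed: int = 0,
    one_se: bool = True,
):
    """Pick the penalty maximizing mean cross-validated AUC.

    Ties break toward the larger penalty, i.e. the sparser model. With
    ``one_se`` (default) a tie is any penalty whose mean AUC lies within one
    standard error of the best — the usual one-SE rule, which keeps noise-only
    data at the all-zero end of the path instead of an arbitrary overfit
    penalty; with ``one_se=False`` only exact ties count. Returns
    ``(lam_star, path)`` where path is a list of dicts with keys
    lam / mean_auc / mean_nonzero for reporting.
    """
    X, y01 = _validate_xy(X, y)
    if lam_grid is None:
        lam_grid = default_lambda_grid(X, y01)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))
    if len(lam_grid) == 0:
        raise ValueError("lam_grid must be non-empty")
    plan = _stratified_plan(y01, rounds, folds, seed)
    aucs = np.zeros((len(plan), len(lam_grid)))
    nnz = np.zeros_like(aucs)
    all_idx = np.arange(len(y01))
    for k, ((r, f), val) in enumerate(sorted(plan.items())):
        train = np.setdiff1d(all_idx, val)
        model = None
        for j in range(len(lam_grid) - 1, -1, -1):  # descend: warm starts
            model = fit_sparse(X[train], y01[train], lam_grid[j], warm_start=model)
            scores = predict_proba(model, X[val])
            aucs[k, j] = roc_auc_score(y01[val], scores) if model.n_nonzero else 0.5
            nnz[k, j] = model.n_nonzero
    mean_auc = aucs.mean(axis=0)
    best_j = int(np.argmax(mean_auc))
    if one_se and len(plan) > 1:
        se = float(aucs[:, best_j].std(ddof=1) / np.sqrt(len(plan)))
        band = mean_auc[best_j] - se
    else:
        band = mean_auc[best_j] - 1e-12
    lam_star = float(lam_grid[np.flatnonzero(mean_auc >= band)[-1]])
    path = [
        {"lam": float(l), "mean_auc": float(a), "mean_nonzero": float(m)}
        for l, a, m in zip(lam_grid, mean_auc, nnz.mean(axis=0))
    ]
    return lam_star, path


@dataclass
class ModelEnsemble:
    """rounds x folds cross-validation ensemble of sparse models."""

    models: list[SparseModel]
    fold_plan: dict  # (round, fold) -> validation sample indices
    val_auc: np.ndarray
    seed: int
    rounds: int
    folds: int
    penalty: float

    def __len__(self) -> int:
        return len(self.models)

    def selection_counts(self, n_features: int) -> np.ndarray:
        counts = np.zeros(n_features, dtype=int)
        for m in self.models:
            counts[m.nonzero_features] += 1
        return counts

    def to_json(self, feature_mz: Optional[Sequence[float]] = None) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "rounds": self.rounds,
                "folds": self.folds,
                "penalty": self.penalty,
                "val_auc": [float(a) for a in self.val_auc],
                "fold_plan": {
                    f"{r},{f}": [int(i) for i in v] for (r, f), v in self.fold_plan.items()
                },
                "models": [m.to_dict(feature_mz) for m in self.models],
            }
        )

    @classmethod
    def from_json(cls, text: str, feature_mz: Optional[Sequence[float]] = None):
        """Rebuild an ensemble from :meth:`to_json` output.

        ``feature_mz`` is required when weights were keyed by m/z strings.
        """
        d = json.loads(text)
        models = []
        for md in d["models"]:
            w = md["weights"]
            if isinstance(w, dict):
                if feature_mz is None:
                    raise ValueError("feature_mz needed to decode keyed weights")
                weights = np.asarray([w[f"{m:.4f}"] for m in feature_mz])
            else:
                weights = np.asarray(w, dtype=float)
            wstd = weights.copy()
            models.append(
                SparseModel(weights=weights, intercept=md["intercept"],
                            penalty=md["penalty"], weights_std=wstd)
            )
        return cls(
            models=models,
            fold_plan={
                tuple(map(int, k.split(","))): np.asarray(v, dtype=int)
                for k, v in d["fold_plan"].items()
            },
            val_auc=np.asarray(d["val_auc"], dtype=float),
            seed=d["seed"],
            rounds=d["rounds"],
            folds=d["folds"],
            penalty=d["penalty"],
        )


def train_ensemble(
    X: np.ndarray,
    y: Sequence,
    lam: float,
    rounds: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> ModelEnsemble:
    """Fit the rounds x folds CV ensemble at a fixed penalty.

    Model (r, f) is trained on everything except fold f of round r and scored
    by AUC on that held-out fold only. Reproducible from ``seed``.
    """
    X, y01 = _validate_xy(X, y)
    if rounds < 1 or folds < 1:
        raise ValueError("rounds and folds must be >= 1")
    plan = _stratified_plan(y01, rounds, folds, seed)
    all_idx = np.arange(len(y01))
    models, val_auc = [], []
    for (r, f), val in sorted(plan.items()):
        train = np.setdiff1d(all_idx, val)
        model = fit_sparse(X[train], y01[train], lam)
        scores = predict_proba(model, X[val])
        if len(np.unique(y01[val])) < 2:
            auc = np.nan  # e.g. leave-one-out folds: AUC undefined
        else:
            auc = roc_auc_score(y01[val], scores) if model.n_nonzero else 0.5
        models.append(model)
        val_auc.append(auc)
    return ModelEnsemble(
        models=models,
        fold_plan=plan,
        val_auc=np.asarray(val_auc),
        seed=seed,
        rounds=rounds,
        folds=folds,
        penalty=lam,
    )


def select_optimized_model(ensemble: ModelEnsemble) -> tuple[SparseModel, int]:
    """The ensemble member with the best validation AUC.

    Ties break toward fewer nonzero features, then the lower model index.
    Returns ``(model, index)``.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    aucs = np.where(np.isnan(ensemble.val_auc), -np.inf, ensemble.val_auc)
    keys = [
        (-aucs[i], ensemble.models[i].n_nonzero, i) for i in range(len(ensemble))
    ]
    idx = min(range(len(keys)), key=keys.__getitem__)
    return ensemble.models[idx], idx


def reference_classifiers(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    y_test: Sequence,
    seed: int = 0,
) -> dict[str, float]:
    """Test AUCs of five standard comparator classifiers at default settings.

    Decision tree, unpenalized logistic regression, RBF SVM (decision-function
    scores), kNN, and random forest, all from scikit-learn.
    """
    _, yte = _validate_xy(np.asarray(X_test, dtype=float), y_test)
    if len(np.unique(yte)) < 2:
        raise ValueError("test set must contain both classes")
    _, ytr = _validate_xy(np.asarray(X_train, dtype=float), y_train)
    out = {}
    methods = {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "logistic_regression": LogisticRegression(C=np.inf, max_iter=2000),
        "svm": SVC(kernel="rbf", random_state=seed),
        "knn": KNeighborsClassifier(),
        "random_forest": RandomForestClassifier(random_state=seed),
    }
    for name, clf in methods.items():
        clf.fit(X_train, ytr)
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(X_test)[:, 1]
        else:
            scores = clf.decision_function(X_test)
        out[name] = float(roc_auc_score(yte, scores))
    return out
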