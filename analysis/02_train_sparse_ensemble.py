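#!/usr/bin/env python
"""Train the sparse-learning diagnostic ensemble on a fingerprint matrix.

Tunes the L1 penalty by cross-validated AUC (one-SE rule), trains the
20-round x 5-fold ensemble of 100 L1-logistic models, reports the mean
held-out AUC, and compares against the five standard reference classifiers on
a held-out split.

Reads:  results/cohort/features.csv + manifest.csv  (from 01)
Writes: results/ensemble.json, results/lambda_path.csv, results/reference_aucs.csv
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from smfdiag.io import read_feature_matrix, read_manifest
from smfdiag.sparse import (
    predict_proba,
    reference_classifiers,
    select_optimized_model,
    train_ensemble,
    tune_penalty,
)
from smfdiag.metrics import roc_auc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--rounds", type=int, default=20)
    ap.add_argument("--folds", type=int, default=5)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    manifest = read_manifest(args.cohort / "manifest.csv")
    matrix = read_feature_matrix(args.cohort / "features.csv", manifest)
    y = np.asarray([1 if g == "case" else 0 for g in matrix.labels])
    X = np.log1p(matrix.values)

    lam, path = tune_penalty(X, y, rounds=2, folds=args.folds, seed=args.seed)
    pd.DataFrame(path).to_csv(args.outdir / "lambda_path.csv", index=False)
    print(f"penalty tuned on {len(path)}-point grid: lambda* = {lam:.4g} "
          f"(one-SE rule over {2 * args.folds} folds)")

    ens = train_ensemble(X, y, lam, rounds=args.rounds, folds=args.folds, seed=args.seed)
    (args.outdir / "ensemble.json").write_text(ens.to_json(matrix.feature_mz))
    best, best_idx = select_optimized_model(ens)
    print(f"{len(ens)} models trained; mean validation AUC "
          f"{np.nanmean(ens.val_auc):.3f} (sd {np.nanstd(ens.val_auc):.3f})")
    print(f"optimized model: index {best_idx}, validation AUC "
          f"{ens.val_auc[best_idx]:.3f}, {best.n_nonzero} nonzero features")

    # reference classifiers on a single stratified split
    itr, ite = train_test_split(np.arange(len(y)), test_size=0.3,
                                stratify=y, random_state=args.seed)
    refs = reference_classifiers(X[itr], y[itr], X[ite], y[ite], seed=args.seed)
    sparse_auc, _ = roc_auc(predict_proba(best, X[ite]), y[ite])
    refs_out = {"sparse_learning": float(sparse_auc), **refs}
    pd.Series(refs_out, name="auc").rename_axis("method").to_csv(
        args.outdir / "reference_aucs.csv"
    )
    print("held-out AUC by method: "
          + ", ".join(f"{k} {v:.3f}" for k, v in refs_out.items()))


if __name__ == "__main__":
    main()
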