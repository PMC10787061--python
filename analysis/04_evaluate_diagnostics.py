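#!/usr/bin/env python
"""Diagnostic read-outs: ROC/CI, operating point, panel fidelity, PCA, figures.

Evaluates the optimized ensemble model (full fingerprint) and the biomarker
panel on the cohort: AUC with stratified-bootstrap 95% CI, Youden
sensitivity/specificity, the panel-vs-full-profile AUC comparison with a
paired-bootstrap p-value, single-marker AUCs, and a PCA score plot of the
panel columns.

Reads:  results/cohort/*, results/ensemble.json, results/panel.json
Writes: results/report.json, results/figures/{roc,probability,pca}.png
"""

import argparse
import json
from pathlib import Path

import numpy as np

from smfdiag.io import read_feature_matrix, read_manifest
from smfdiag.metrics import compare_auc, diagnostic_report, pca_scores, roc_auc
from smfdiag.plots import plot_pca, plot_probability_scatter, plot_roc
from smfdiag.sparse import ModelEnsemble, SparseModel, predict_proba, select_optimized_model


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap", type=int, default=2000)
    args = ap.parse_args()

    manifest = read_manifest(args.cohort / "manifest.csv")
    matrix = read_feature_matrix(args.cohort / "features.csv", manifest)
    y = np.asarray([1 if g == "case" else 0 for g in matrix.labels])
    X = np.log1p(matrix.values)
    ens = ModelEnsemble.from_json(
        (args.outdir / "ensemble.json").read_text(), matrix.feature_mz
    )
    best, best_idx = select_optimized_model(ens)

    probs = predict_proba(best, X)
    full = diagnostic_report(probs, y, B=args.bootstrap, seed=args.seed)
    print("full fingerprint (optimized model, in-cohort):", full.summary())

    panel_d = json.loads((args.outdir / "panel.json").read_text())
    pidx = np.asarray(panel_d["feature_idx"], dtype=int)
    pmz = np.asarray(panel_d["feature_mz"], dtype=float)
    w = np.asarray([panel_d["model"]["weights"][f"{m:.4f}"] for m in pmz])
    pmodel = SparseModel(weights=w, intercept=panel_d["model"]["intercept"],
                         penalty=panel_d["model"]["penalty"])
    pprobs = predict_proba(pmodel, X[:, pidx])
    panel_rep = diagnostic_report(pprobs, y, B=args.bootstrap, seed=args.seed)
    print("biomarker panel:", panel_rep.summary())
    p_cmp = compare_auc(probs, pprobs, y, B=500, seed=args.seed)
    print(f"panel AUC loss {full.auc - panel_rep.auc:+.3f} "
          f"(paired bootstrap p = {p_cmp:.3f})")
    singles = {}
    for j, mz in zip(pidx, pmz):
        a, _ = roc_auc(X[:, j], y)
        singles[f"{mz:.4f}"] = round(float(max(a, 1 - a)), 3)
    print("single-marker AUCs:", singles)

    figdir = args.outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    _, full_curve = roc_auc(probs, y)
    _, panel_curve = roc_auc(pprobs, y)
    plot_roc(
        {"full fingerprint": (full_curve[0], full_curve[1], full.auc),
         "4-marker panel": (panel_curve[0], panel_curve[1], panel_rep.auc)},
        figdir / "roc.png",
    )
    plot_probability_scatter(probs, matrix.labels, figdir / "probability.png",
                             threshold=full.threshold)
    scores, evr = pca_scores(X[:, pidx])
    plot_pca(scores, matrix.labels, evr, figdir / "pca.png")
    print(f"figures in {figdir}")

    payload = {
        "full_profile": json.loads(full.to_json()),
        "panel": json.loads(panel_rep.to_json()),
        "panel_vs_full_p": p_cmp,
        "single_marker_auc": singles,
        "ensemble_mean_val_auc": float(np.nanmean(ens.val_auc)),
        "optimized_model_index": int(best_idx),
    }
    (args.outdir / "report.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {args.outdir}/report.json")


if __name__ == "__main__":
    main()
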