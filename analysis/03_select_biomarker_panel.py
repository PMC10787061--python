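#!/usr/bin/env python
"""Run the feature funnel: full fingerprint -> stable features -> k-marker panel.

Summarizes the trained ensemble into per-feature selection frequencies, mean
absolute weights, univariate Mann-Whitney p-values and fold changes; keeps
features selected in >= 95% of models with p < 0.05; refits the top-k as a
standalone panel diagnostic; and checks the panel against the planted ground
truth.

Reads:  results/cohort/* (01), results/ensemble.json (02)
Writes: results/stability.csv, results/panel.json
"""

import argparse
import json
from pathlib import Path

import numpy as np

from smfdiag import PeakCatalog
from smfdiag.io import read_feature_matrix, read_manifest
from smfdiag.sparse import ModelEnsemble
from smfdiag.stability import build_panel, select_stable, stability_profile


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--ensemble", type=Path, default=Path("results/ensemble.json"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--panel-size", type=int, default=4)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    manifest = read_manifest(args.cohort / "manifest.csv")
    matrix = read_feature_matrix(args.cohort / "features.csv", manifest)
    y = np.asarray([1 if g == "case" else 0 for g in matrix.labels])
    X = np.log1p(matrix.values)
    ens = ModelEnsemble.from_json(args.ensemble.read_text(), matrix.feature_mz)

    profile = stability_profile(ens, X, y, matrix.feature_mz, intensity_values=matrix.values)
    profile.to_frame().to_csv(args.outdir / "stability.csv", index=False)
    freq_min = int(np.ceil(0.95 * len(ens)))
    stable = select_stable(profile, freq_min=freq_min, alpha=0.05)
    print(f"feature funnel: {matrix.n_features} aligned features "
          f"-> {len(stable)} stable (frequency >= {freq_min}/{len(ens)}, p < 0.05) "
          f"-> panel of {min(args.panel_size, len(stable))}")

    if len(stable) == 0:
        print("no stable features; stopping")
        return
    k = min(args.panel_size, len(stable))
    panel = build_panel(X, y, stable, k=k, seed=args.seed, feature_mz=matrix.feature_mz)
    (args.outdir / "panel.json").write_text(panel.to_json())
    print("panel m/z: " + ", ".join(f"{m:.3f}" for m in panel.feature_mz))
    for mz, f, p, fc in zip(
        profile.feature_mz[panel.feature_idx],
        profile.selection_frequency[panel.feature_idx],
        profile.p_value[panel.feature_idx],
        profile.fold_change[panel.feature_idx],
    ):
        print(f"  m/z {mz:9.3f}  frequency {f:3d}  p {p:.2e}  fold change {fc:.2f}")

    truth_path = args.cohort / "truth.json"
    if truth_path.exists():
        catalog = PeakCatalog.from_json(truth_path.read_text())
        planted = catalog.mz_center[catalog.informative_idx]
        hits = sum(
            1 for m in panel.feature_mz if np.min(np.abs(planted - m)) < 0.1
        )
        print(f"ground truth: {hits}/{len(panel.feature_mz)} panel members are planted markers")


if __name__ == "__main__":
    main()
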