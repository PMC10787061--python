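"""End-to-end orchestration: simulate -> preprocess -> train -> select -> evaluate.

A run is driven by a :class:`RunConfig` (YAML round-trippable); every run
directory receives the fully resolved config, a JSON-lines log with all seeds,
and the stage artifacts (feature matrix CSV, ensemble JSON, stability CSV,
panel JSON, diagnostic report JSON). Identical config + seed reproduces
numerically identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .io import (
    read_feature_matrix,
    read_manifest,
    read_spectrum,
    write_feature_matrix,
    write_manifest,
)
from .metrics import diagnostic_report
from .preprocess import FeatureMatrix, build_feature_matrix, cosine_qc
from .simulate import SimConfig, build_catalog, iter_cohort
from .sparse import (
    predict_proba,
    select_optimized_model,
    train_ensemble,
    tune_penalty,
)
from .stability import build_panel, evaluate_panel, select_stable, stability_profile

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0

    # input: either simulate, or point at spectra + manifest
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    spectra_dir: Optional[str] = None
    manifest: Optional[str] = None
    matrix_csv: Optional[str] = None  # skip preprocessing if given

    # preprocessing
    smooth_window: int = 7
    smooth_polyorder: int = 2
    baseline_half_window: int = 100
    snr_min: float = 3.0
    min_separation: float = 0.045
    align_tolerance: float = 0.1
    norm_method: str = "tic"
    log1p: bool = True

    # ensemble
    rounds: int = 20
    folds: int = 5
    tune_rounds: int = 2
    lambda_grid_size: int = 10

    # selection (freq_min counts per 100 models and is rescaled to the ensemble)
    freq_min: int = 95
    alpha: float = 0.05
    panel_k: int = 4

    # evaluation
    bootstrap: int = 2000

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            sim["mz_range"] = tuple(sim["mz_range"])
            sim["fold_change_range"] = tuple(sim["fold_change_range"])
            cfg.sim = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _log(handle, stage: str, **kv) -> None:
    rec = {"t": round(time.time(), 3), "stage": stage, **kv}
    handle.write(json.dumps(rec) + "\n")
    handle.flush()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Stages: (optional) simulate -> preprocess -> train ensemble -> stability
    selection -> panel -> diagnostic report. Any stage failure raises with the
    stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        f"# smfdiag {__version__}  config_hash={config.config_hash()}\n" + config.to_yaml()
    )
    log = open(out / "log.jsonl", "w")
    _log(log, "start", version=__version__, config_hash=config.config_hash(),
         seed=config.seed)

    stage = "input"
    try:
        if config.matrix_csv is not None:
            manifest = read_manifest(config.manifest) if config.manifest else None
            matrix = read_feature_matrix(config.matrix_csv, manifest)
            labels = matrix.labels
        else:
            if config.simulate:
                stage = "simulate"
                sim = dataclasses.replace(config.sim, seed=config.seed)
                spectra_labels = iter_cohort(sim)
                spectra, labels = [], []
                # stream: preprocess each spectrum as it is generated
                stage = "preprocess"
                from .preprocess import preprocess_spectrum, align_peaks, normalize

                peaklists = []
                for spec, grp in spectra_labels:
                    peaklists.append(
                        preprocess_spectrum(
                            spec,
                            config.smooth_window,
                            config.smooth_polyorder,
                            config.baseline_half_window,
                            config.snr_min,
                            config.min_separation,
                        )
                    )
                    labels.append(grp)
                matrix = normalize(
                    align_peaks(peaklists, config.align_tolerance, labels),
                    config.norm_method,
                )
                write_manifest(matrix.sample_ids, labels, out / "manifest.csv")
            else:
                stage = "read_spectra"
                manifest = read_manifest(config.manifest)
                spectra = [
                    read_spectrum(Path(config.spectra_dir) / f"{sid}.csv")
                    for sid in manifest["sample_id"]
                ]
                labels = list(manifest["group"])
                stage = "preprocess"
                matrix = build_feature_matrix(
                    spectra,
                    labels,
                    tolerance=config.align_tolerance,
                    norm_method=config.norm_method,
                    smooth_window=config.smooth_window,
                    smooth_polyorder=config.smooth_polyorder,
                    baseline_half_window=config.baseline_half_window,
                    snr_min=config.snr_min,
                    min_separation=config.min_separation,
                )
            write_feature_matrix(matrix, out / "features.csv")
            qc = cosine_qc(matrix, labels)
            _log(log, "preprocess", n_samples=matrix.n_samples,
                 n_features=matrix.n_features,
                 qc_frac_above_0p9=float(np.mean(qc > 0.9)))

        y = np.asarray([1 if g == "case" else 0 for g in labels])
        X = np.log1p(matrix.values) if config.log1p else matrix.values

        stage = "train"
        lam, path = tune_penalty(
            X, y, rounds=config.tune_rounds, folds=config.folds, seed=config.seed
        )
        ensemble = train_ensemble(
            X, y, lam, rounds=config.rounds, folds=config.folds, seed=config.seed
        )
        (out / "ensemble.json").write_text(ensemble.to_json(matrix.feature_mz))
        _log(log, "train", lam=lam, n_models=len(ensemble),
             mean_val_auc=float(ensemble.val_auc.mean()), path=path)

        stage = "select"
        profile = stability_profile(ensemble, X, y, matrix.feature_mz, intensity_values=matrix.values)
        profile.to_frame().to_csv(out / "stability.csv", index=False)
        # freq_min is specified per 100 models; rescale to the ensemble size
        freq_min = int(np.ceil(config.freq_min / 100 * len(ensemble)))
        stable = select_stable(profile, freq_min, config.alpha)
        _log(log, "select", n_stable=int(len(stable)))

        stage = "panel"
        k = min(config.panel_k, len(stable))
        panel_report = None
        if k >= 1:
            panel = build_panel(X, y, stable, k=k, seed=config.seed,
                                feature_mz=matrix.feature_mz)
            (out / "panel.json").write_text(panel.to_json())
            disc, _, single = evaluate_panel(
                panel, X, y, rounds=config.rounds, folds=config.folds,
                seed=config.seed, bootstrap=config.bootstrap,
            )
            panel_report = {"panel": json.loads(panel.to_json()),
                            "discovery": json.loads(disc.to_json()),
                            "single_marker_auc": single}

        stage = "evaluate"
        best, best_idx = select_optimized_model(ensemble)
        probs = predict_proba(best, X)
        report = diagnostic_report(probs, y, B=config.bootstrap, seed=config.seed)
        payload = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "optimized_model_index": int(best_idx),
            "ensemble_mean_val_auc": float(ensemble.val_auc.mean()),
            "full_profile": json.loads(report.to_json()),
        }
        if panel_report is not None:
            payload["panel"] = panel_report
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        _log(log, "evaluate", auc=report.auc, ci=[report.ci_low, report.ci_high])
    except Exception as e:
        _log(log, "error", failed_stage=stage, error=str(e))
        log.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    _log(log, "done")
    log.close()
    return out
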