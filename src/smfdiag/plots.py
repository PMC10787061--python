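"""Figure helpers: ROC curves, probability scatter, PCA score plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc(curves: dict, path) -> None:
    """curves: name -> (fpr, tpr, auc)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, (fpr, tpr, auc) in curves.items():
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_probability_scatter(probs, labels, path, threshold: float = 0.5) -> None:
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    rng = np.random.default_rng(0)
    for i, g in enumerate(np.unique(labels)):
        p = np.asarray(probs)[labels == g]
        ax.scatter(i + rng.uniform(-0.18, 0.18, len(p)), p, s=8, alpha=0.5, label=str(g))
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xticks(range(len(np.unique(labels))), np.unique(labels))
    ax.set_ylabel("predicted probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(scores, labels, evr, path) -> None:
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for g in np.unique(labels):
        pts = np.asarray(scores)[labels == g]
        ax.scatter(pts[:, 0], pts[:, 1], s=10, alpha=0.6, label=str(g))
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
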