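"""Basic figures: ROC curve and serum-score dot plots.

Matplotlib is used with the Agg backend so figures can be written headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import ROCResult


def plot_roc(result: ROCResult, path: str, title: str = "ROC curve") -> str:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.points["fpr"], result.points["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC = {result.auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_serum_scores(per_sample: pd.DataFrame, path: str, title: str = "Serum scores") -> str:
    """Dot plot of per-sample serum scores by cohort with median/IQR bars."""
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for i, (cohort, grp) in enumerate(per_sample.groupby("cohort")):
        x = i + rng.uniform(-0.15, 0.15, len(grp))
        ax.scatter(x, grp["serum_score"], s=10, alpha=0.6)
        med = grp["serum_score"].median()
        q25, q75 = np.percentile(grp["serum_score"], [25, 75])
        ax.hlines(med, i - 0.25, i + 0.25, colors="k", lw=1.5)
        ax.hlines([q25, q75], i - 0.15, i + 0.15, colors="k", lw=0.8)
    ax.set_xticks(range(per_sample["cohort"].nunique()))
    ax.set_xticklabels(sorted(per_sample["cohort"].unique()))
    ax.set_ylabel("serum score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
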