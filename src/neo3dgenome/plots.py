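"""Optional figure outputs (requires matplotlib).

Three views of the analysis: per-chromosome mean contact frequency of
pos-pos vs neg-neg epitope pairs with significance stars, genome-wide CF
distributions of the three pair groups, and ROC / precision-recall
curves of the combined score against the baseline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import pr_aupr, roc_auc
from .spatial import ChromosomeComparison, PairGroupSummary


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_intra_chromosome_means(
    comparisons: Mapping[str, ChromosomeComparison], path: str | Path
) -> None:
    """Grouped bars of mean CF (pos-pos vs neg-neg) per chromosome; a
    star marks chromosomes with p below the significance threshold."""
    plt = _plt()
    chroms = list(comparisons)
    x = np.arange(len(chroms))
    pos_means = [comparisons[c].pos_pos.mean for c in chroms]
    neg_means = [comparisons[c].neg_neg.mean for c in chroms]
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(chroms)), 3.2))
    ax.bar(x - 0.2, pos_means, width=0.4, label="pos-pos")
    ax.bar(x + 0.2, neg_means, width=0.4, label="neg-neg")
    for i, c in enumerate(chroms):
        if comparisons[c].significant:
            top = max(pos_means[i], neg_means[i])
            ax.text(x[i], top * 1.02, "*", ha="center", fontsize=14)
    ax.set_xticks(x, chroms, rotation=45)
    ax.set_ylabel("mean contact frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_inter_chromosome_distributions(
    summaries: Mapping[str, PairGroupSummary], path: str | Path
) -> None:
    """Box plot of genome-wide CF distributions for the three pair groups."""
    plt = _plt()
    groups = ["pos-pos", "pos-neg", "neg-neg"]
    data = [summaries[g].cf_values for g in groups if g in summaries]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.boxplot(data, tick_labels=[g for g in groups if g in summaries], showfliers=False)
    ax.set_ylabel("contact frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc_pr(loocv_table: pd.DataFrame, path_prefix: str | Path) -> tuple[Path, Path]:
    """ROC and PR curves for combined vs baseline-only scoring; returns
    the two file paths (``<prefix>_roc.png``, ``<prefix>_pr.png``)."""
    plt = _plt()
    labels = loocv_table["label"].to_numpy()
    roc_path = Path(f"{path_prefix}_roc.png")
    pr_path = Path(f"{path_prefix}_pr.png")

    fig, ax = plt.subplots(figsize=(3.6, 3.4))
    for method, col in (("3D-genome + baseline", "combined_score"),
                        ("baseline only", "baseline_score")):
        fpr, tpr, a = roc_auc(loocv_table[col].to_numpy(), labels)
        ax.plot(fpr, tpr, label=f"{method} (AUC {a:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="gray")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(roc_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(3.6, 3.4))
    for method, col in (("3D-genome + baseline", "combined_score"),
                        ("baseline only", "baseline_score")):
        precision, recall, a = pr_aupr(loocv_table[col].to_numpy(), labels)
        ax.plot(recall, precision, label=f"{method} (AUPR {a:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(pr_path, dpi=150)
    plt.close(fig)
    return roc_path, pr_path
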