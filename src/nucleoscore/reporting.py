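"""Report rendering: confusion heatmaps, ROC curves, agreement curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from nucleoscore.model_selection import EvaluationReport

__all__ = ["plot_roc", "plot_confusion", "plot_agreement_curves", "render_report"]

_ROC_GRID = np.linspace(0, 1, 101)


def plot_roc(report: EvaluationReport, path: str | Path) -> None:
    """Per-fold ROC curves plus the mean curve with a std band."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    interp = []
    for fold in report.folds:
        if not fold.roc_points:
            continue
        fpr, tpr = zip(*fold.roc_points)
        ax.plot(fpr, tpr, alpha=0.45, lw=1,
                label=f"fold {fold.fold_index} (AUC {fold.auc:.2f})")
        interp.append(np.interp(_ROC_GRID, fpr, tpr))
    if interp:
        arr = np.vstack(interp)
        mean, std = arr.mean(axis=0), arr.std(axis=0)
        ax.plot(_ROC_GRID, mean, color="k", lw=2,
                label=f"mean (AUC {report.auc_mean:.2f} ± {report.auc_std:.2f})")
        ax.fill_between(_ROC_GRID, np.clip(mean - std, 0, 1),
                        np.clip(mean + std, 0, 1), color="gray", alpha=0.3)
    ax.plot([0, 1], [0, 1], "r:", label="classification by chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_confusion(report: EvaluationReport, path: str | Path) -> None:
    cm = np.asarray(report.pooled_confusion)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > cm.max() / 2 else "black")
    ax.set_xticks([0, 1], ["non-PTC-like", "PTC-like"])
    ax.set_yticks([0, 1], ["non-PTC-like", "PTC-like"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_agreement_curves(table: pd.DataFrame, path: str | Path) -> None:
    """Dual panel: accuracies and subset sizes vs the agreement threshold."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    t = table["threshold"]
    if table["classifier_accuracy"].notna().any():
        ax1.plot(t, table["classifier_accuracy"], "o-", label="classifier accuracy")
    ax1.plot(t, table["mean_c_i"], "s-", color="green", label="mean expert rating")
    ax1.plot(t, table["distribution_accuracy"], "x-", color="red",
             label="distribution accuracy")
    ax1.set_xlabel("minimal pathologist agreement level")
    ax1.set_ylabel("accuracy")
    ax1.legend(fontsize=8)
    ax2.plot(t, table["n_ptc"], "o-", label="PTC-like")
    ax2.plot(t, table["n_non_ptc"], "s-", color="orange", label="non-PTC-like")
    ax2.set_xlabel("minimal pathologist agreement level")
    ax2.set_ylabel("samples")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_report(
    report: EvaluationReport,
    outdir: str | Path,
    expert_table: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the standard plot set (PNG + SVG) and CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for ext in ("png", "svg"):
        p = outdir / f"roc.{ext}"
        plot_roc(report, p)
        written.append(p)
        p = outdir / f"confusion.{ext}"
        plot_confusion(report, p)
        written.append(p)
    pd.DataFrame(
        np.asarray(report.pooled_confusion),
        index=["true_nonPTC", "true_PTC"],
        columns=["pred_nonPTC", "pred_PTC"],
    ).to_csv(outdir / "confusion.csv")
    written.append(outdir / "confusion.csv")
    roc_rows = [
        {"fold": f.fold_index, "fpr": fp, "tpr": tp}
        for f in report.folds
        if f.roc_points
        for fp, tp in f.roc_points
    ]
    pd.DataFrame(roc_rows).to_csv(outdir / "roc_points.csv", index=False)
    written.append(outdir / "roc_points.csv")
    if expert_table is not None:
        for ext in ("png", "svg"):
            p = outdir / f"agreement.{ext}"
            plot_agreement_curves(expert_table, p)
            written.append(p)
    return written
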