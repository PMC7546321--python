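"""Optional figures: the LOOCV accuracy surface and the ROC curve.

matplotlib is imported lazily so the core pipeline has no hard
dependency on a plotting backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classify import ClassificationReport, ROCReport

__all__ = ["plot_accuracy_surface", "plot_roc"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_accuracy_surface(
    report: ClassificationReport, path: str | Path
) -> Path:
    """3D view of LOOCV accuracy over the (log2 C, log2 gamma) grid."""
    plt = _mpl()
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    gg, cc = np.meshgrid(report.log2_gamma, report.log2_c)
    ax.plot_surface(cc, gg, 100.0 * report.accuracy_grid,
                    cmap="viridis", edgecolor="none")
    ax.set_xlabel("log2 C")
    ax.set_ylabel("log2 gamma")
    ax.set_zlabel("LOOCV accuracy (%)")
    ax.set_title(
        f"{report.region_id}: best {100 * report.best_accuracy:.1f}% at "
        f"C=2^{report.best_log2_c:.0f}, gamma=2^{report.best_log2_gamma:.0f}"
    )
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_roc(report: ROCReport, path: str | Path) -> Path:
    """ROC curve with the Youden cut-off marked."""
    plt = _mpl()
    order = np.argsort(1.0 - report.spec_sweep)
    fpr = (1.0 - report.spec_sweep)[order]
    tpr = report.sens_sweep[order]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, drawstyle="steps-post",
            label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    at = np.flatnonzero(report.thresholds == report.cutoff)[0]
    ax.plot(1.0 - report.spec_sweep[at], report.sens_sweep[at], "o",
            c="crimson", label=f"cut-off = {report.cutoff:.4f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(report.region_id)
    ax.legend(loc="lower right")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
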