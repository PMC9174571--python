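"""Confusion-matrix rendering (true class on rows, predicted on columns)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["plot_confusion_matrix"]


def plot_confusion_matrix(
    confusion: np.ndarray,
    path: str | Path,
    title: str = "",
    class_labels: list[str] | None = None,
):
    """Render a validation confusion matrix to PNG or SVG.

    Diagonal entries are correct estimates; output files carry no
    timestamp metadata so reruns are byte-identical.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = np.asarray(confusion)
    n = cm.shape[0]
    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * n, 1.0 + 0.5 * n))
    ax.imshow(cm, cmap="Blues")
    thresh = cm.max() / 2 if cm.max() else 0.5
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    fontsize=8,
                    color="white" if cm[i, j] > thresh else "black")
    labels = class_labels or [str(i) for i in range(n)]
    ax.set_xticks(range(n), labels, fontsize=7)
    ax.set_yticks(range(n), labels, fontsize=7)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    meta = {"Date": None} if path.suffix == ".svg" else {"Software": None}
    fig.savefig(path, dpi=150, metadata=meta)
    plt.close(fig)
    return path
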