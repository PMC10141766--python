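"""Small plotting helpers (confusion matrices and feature distributions)."""

from __future__ import annotations

import numpy as np

from .eeg_io import CLASS_ORDER


def plot_confusion(confusion: np.ndarray, title: str = "", ax=None):
    """Heatmap of a 4x4 confusion matrix (rows = true class)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(confusion, cmap="Blues")
    ax.set_xticks(range(4), CLASS_ORDER, rotation=45, ha="right")
    ax.set_yticks(range(4), CLASS_ORDER)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(confusion.shape[0]):
        for j in range(confusion.shape[1]):
            ax.text(j, i, str(confusion[i, j]), ha="center", va="center")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_feature_boxes(feature_table, feature: str = "Hur", ax=None):
    """Per-class box plot of one feature averaged over channels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cols = [c for c in feature_table.matrix.columns
            if c.endswith(f"__{feature}")]
    per_trial = feature_table.matrix[cols].mean(axis=1)
    groups = [per_trial[feature_table.labels == cls] for cls in CLASS_ORDER]
    ax.boxplot(groups, tick_labels=CLASS_ORDER)
    ax.set_ylabel(feature)
    ax.tick_params(axis="x", rotation=30)
    return ax
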