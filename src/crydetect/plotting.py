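"""Timeline and robustness figures (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sequences import EPOCH_MINUTES, SequenceSummary


def plot_timeline(
    annotated: SequenceSummary,
    predicted: SequenceSummary,
    n_epochs: int,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Per-subject strip of annotated vs predicted cry sequences."""
    fig, ax = plt.subplots(figsize=(8, 1.8))
    for y, (summary, color) in enumerate(
        [(annotated, "tab:blue"), (predicted, "tab:orange")]
    ):
        for seq in summary.sequences:
            ax.barh(
                y,
                (seq.end_epoch - seq.start_epoch + 1) * EPOCH_MINUTES,
                left=seq.start_epoch * EPOCH_MINUTES,
                height=0.6,
                color=color,
            )
    ax.set_yticks([0, 1], ["annotated", "predicted"])
    ax.set_xlim(0, n_epochs * EPOCH_MINUTES)
    ax.set_xlabel("time (min)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cumulative_curves(curves, path: str | Path, title: str | None = None) -> None:
    """Cumulative cry-count curves; the reference is drawn first."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, curve in enumerate(curves):
        minutes = np.arange(1, len(curve) + 1) * EPOCH_MINUTES
        kwargs = {"lw": 2.5, "color": "lightblue"} if i == 0 else {"lw": 1.0}
        ax.plot(minutes, curve.counts, label=curve.label, **kwargs)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative cry epochs")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
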