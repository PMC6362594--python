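"""Static QC figures: recall curves, the GP fit, and before/after AURC scatter."""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .benchmark import RecallResult
from .gpr_correction import BiasModel, predict_bias

__all__ = ["plot_recall_curves", "plot_gp_fit", "plot_aurc_scatter"]


def plot_recall_curves(results: Iterable[RecallResult], path: Optional[str] = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    for rc in results:
        n = len(rc.curve)
        ax.plot(np.arange(1, n + 1) / n, rc.curve,
                label=f"{rc.gene_set} (AURC={rc.aurc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("ranked genes (most depleted first, fraction)")
    ax.set_ylabel("recall")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gp_fit(model: BiasModel, path: Optional[str] = None):
    """Segment mean fold change vs ratio with the GP mean and +-1 sd band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(model.train_x.min(), model.train_x.max(), 200)
    mean, sd = predict_bias(model, grid)
    ax.fill_between(grid, mean - sd, mean + sd, color="gold", alpha=0.5,
                    label="GPR sd")
    ax.plot(grid, mean, c="tab:red", label="GPR mean")
    ax.scatter(model.train_x, model.train_y, s=12, c="tab:blue", alpha=0.7,
               label="segments")
    ax.set_xlabel("segment copy-number ratio")
    ax.set_ylabel("segment mean log2 fold change")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_aurc_scatter(pairs, path: Optional[str] = None):
    """Original vs corrected AURC per stratum (diagonal = no change)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pairs["aurc_a"], pairs["aurc_b"], s=20)
    for _, row in pairs.iterrows():
        ax.annotate(row["stratum"], (row["aurc_a"], row["aurc_b"]), fontsize=7)
    lim = (0, 1)
    ax.plot(lim, lim, ls="--", c="grey", lw=0.8)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("AURC original")
    ax.set_ylabel("AURC corrected")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
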