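"""Matplotlib renderings of correlograms, RVI curves, ROC curves and
upscaled smooth components.  Import is deferred so headless library use
never touches a display backend."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def correlogram_plot(profiles: dict, path, title="Residual autocorrelation"):
    """Moran's I vs distance for one or more labelled profiles."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.bin_centers, prof.moran_i, marker="o", label=label)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("distance (cells)")
    ax.set_ylabel("Moran's I")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rvi_plot(importance, path):
    """Relative variable importance vs wavelet scale."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for var in importance.index:
        ax.plot(importance.columns, importance.loc[var], marker="o", label=var)
    ax.set_xlabel("scale (level)")
    ax.set_ylabel("relative importance")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_plot(curve, path):
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(1.0 - curve.specificity, curve.sensitivity, marker=".")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    kind = "spatial" if curve.spatial else "classical"
    ax.set_title(f"{kind} ROC, AUC = {curve.auc:.3f}, TSS = {curve.tss:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def upscale_heatmap(matrix: np.ndarray, path, scale: int):
    """Smooth component as a grayscale map (values increase black->white)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(matrix, cmap="gray", origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"smooth component, level {scale}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
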