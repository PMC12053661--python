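"""Optional PNG rendering of heatmaps, profiles and typhoon plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .profiles import TssHeatmap, TyphoonProfile
from .types import Signal1D


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_heatmap(hm: TssHeatmap, path: str | Path, vmax_quantile: float = 0.98) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 8))
    vmax = np.quantile(hm.matrix, vmax_quantile) if hm.matrix.size else 1.0
    ax.imshow(
        hm.matrix,
        aspect="auto",
        cmap="Blues",
        vmax=max(vmax, 1e-9),
        extent=(-hm.w_up, hm.w_down, len(hm.gene_ids), 0),
    )
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("genes (decreasing activity)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(sig: Signal1D, path: str | Path, label: str = "signal") -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(sig.positions, sig.values, lw=1)
    ax.set_xlabel("relative position (bp)")
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_typhoon(prof: TyphoonProfile, path: str | Path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    order = np.argsort(prof.density)
    ax.scatter(
        prof.positions[order],
        prof.lengths[order],
        c=prof.density[order],
        s=4,
        cmap="viridis",
    )
    ax.set_xlabel("midpoint position (bp)")
    ax.set_ylabel("fragment length (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
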