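"""Optional plot side-outputs (PNG/SVG); never part of the testable contract."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_R_histogram", "plot_distance_scatter", "plot_maps"]


def plot_R_histogram(result, path: str | Path) -> Path:
    """Histogram of the J Procrustes correlations of the candidate references."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.R_values(), bins=50, color="steelblue", edgecolor="white")
    ax.set_xlabel("Procrustes correlation R")
    ax.set_ylabel("number of candidate references")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_distance_scatter(comparison, path: str | Path) -> Path:
    """ALR distances against the exact logratio distances, with the identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(comparison.exact, comparison.approx, s=8, alpha=0.6)
    lim = [0, max(comparison.exact.max(), comparison.approx.max()) * 1.05]
    ax.plot(lim, lim, color="grey", lw=1)
    ax.set_xlabel("exact logratio distance")
    ax.set_ylabel("ALR distance")
    ax.set_title(f"r = {comparison.pearson_r:.4f}, {comparison.n_pairs} pairs")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_maps(exact_config, alr_config, path: str | Path) -> Path:
    """Side-by-side 2-D ordination maps of the exact and ALR geometries."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for ax, cfg, title in zip(axes, (exact_config, alr_config), ("exact logratio geometry (LRA)", "ALR geometry (PCA)")):
        xy = cfg.coordinates[:, :2]
        ax.scatter(xy[:, 0], xy[:, 1], s=15)
        for sid, (x, y) in zip(cfg.sample_ids, xy):
            ax.annotate(sid, (x, y), fontsize=7, alpha=0.8)
        pct = cfg.explained[:2] * 100
        ax.set_xlabel(f"axis 1 ({pct[0]:.1f}%)")
        ax.set_ylabel(f"axis 2 ({pct[1]:.1f}%)")
        ax.set_title(title)
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
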