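"""Optional matplotlib figures (heatmaps, mean-profile curves, KM plots).

Imported lazily by the CLI so headless library use never touches matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_profile_heatmap(values: np.ndarray, positions: np.ndarray, path: str | Path,
                         title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap="viridis",
                   extent=[positions[0], positions[-1], values.shape[0], 0])
    ax.set_xlabel("position relative to summit (bp)")
    ax.set_ylabel("sites")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mean RPM")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """One curve per row of a (label x position) mean-profile table."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    x = profiles.columns.astype(float)
    for label, row in profiles.iterrows():
        ax.plot(x, row.values, label=str(label), lw=1.2)
    ax.set_xlabel("position relative to summit (bp)")
    ax.set_ylabel("mean RPM")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(km_table: pd.DataFrame, path: str | Path) -> None:
    """Step plot of per-cluster KM curves from the pipeline's km_clusters.tsv."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, grp in km_table.groupby("cluster"):
        ax.step(grp["time"], grp["survival"], where="post", label=f"cluster {label}")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("relapse-free fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
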