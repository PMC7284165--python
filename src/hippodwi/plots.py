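"""Summary figures: group bar plots and orientation rose histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["group_bar_plot", "orientation_rose"]


def group_bar_plot(table: pd.DataFrame, parameter: str, roi: str, path,
                   groups=("control", "ipsilateral", "contralateral")) -> None:
    """Group means of one parameter in one ROI, SD error bars."""
    sub = table[(table["parameter"] == parameter) & (table["roi"] == roi)]
    means = [sub.loc[sub["group"] == g, "value"].mean() for g in groups]
    sds = [sub.loc[sub["group"] == g, "value"].std() for g in groups]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(groups)), means, yerr=sds, capsize=4,
           color=["#4c72b0", "#c44e52", "#55a868"])
    ax.set_xticks(range(len(groups)), groups, rotation=20)
    ax.set_ylabel(parameter)
    ax.set_title(f"{parameter} in {roi}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def orientation_rose(angles_deg: np.ndarray, path, mu0: float | None = None,
                     bins: int = 18, title: str = "") -> None:
    """Polar histogram of axial orientations, mirrored over 180 degrees."""
    angles = np.asarray(angles_deg, dtype=float) % 180.0
    both = np.concatenate([angles, angles + 180.0])
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(111, projection="polar")
    counts, edges = np.histogram(np.radians(both), bins=2 * bins,
                                 range=(0, 2 * np.pi))
    ax.bar((edges[:-1] + edges[1:]) / 2, counts,
           width=np.diff(edges), color="#4c72b0", alpha=0.8)
    if mu0 is not None:
        for m in (mu0, mu0 + 180.0):
            ax.axvline(np.radians(m), color="#c44e52", lw=2)
    ax.set_yticklabels([])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
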