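"""Figure exports: DAPC scatterplots, within-host frequency histograms, and
wave-trend lines. All functions write a file and return the path; they use the
Agg backend so they run headless."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diversity import AlleleProfile
from .structure_dapc import DapcResult

__all__ = ["plot_dapc_scatter", "plot_allele_frequency_histogram", "plot_wave_trend"]


def _inertia_ellipse(ax, xy: np.ndarray, color, n_std: float = 2.447) -> None:
    """95% inertia ellipse from the group's 2-D covariance."""
    from matplotlib.patches import Ellipse

    if len(xy) < 3:
        return
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))
    w, h = 2 * n_std * np.sqrt(np.maximum(evals[::-1], 0))
    ax.add_patch(
        Ellipse(xy.mean(axis=0), w, h, angle=angle, fill=False, color=color, lw=1)
    )


def plot_dapc_scatter(result: DapcResult, path: str | Path) -> Path:
    """Discriminant axes 1-2 with per-group 95% inertia ellipses."""
    fig, ax = plt.subplots(figsize=(6, 5))
    Z = result.scores
    y = Z[:, 1] if Z.shape[1] > 1 else np.zeros(len(Z))
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(result.groups):
        mask = result.group_labels == g
        color = cmap(gi % 10)
        ax.scatter(Z[mask, 0], y[mask], s=18, color=color, label=str(g))
        _inertia_ellipse(ax, np.column_stack([Z[mask, 0], y[mask]]), color)
    ax.set_xlabel("Discriminant axis 1")
    ax.set_ylabel("Discriminant axis 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_allele_frequency_histogram(profile: AlleleProfile, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(profile.p, bins=np.linspace(0, 1, 41), color="steelblue")
    ax.set_xlabel("Alternative-allele frequency")
    ax.set_ylabel("Segregating sites")
    ax.set_title(profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_wave_trend(table: pd.DataFrame, path: str | Path) -> Path:
    """Median within-host diversity across (year, season, wave)."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    t = table.sort_values(["year", "season", "wave"]).reset_index(drop=True)
    labels = [f"{r.year}-{r.season[0]}-{r.wave}" for r in t.itertuples()]
    ax.plot(range(len(t)), t["median_pi"], marker="o", color="firebrick")
    imputed = t["imputed"].to_numpy(dtype=bool)
    if imputed.any():
        ax.plot(
            np.flatnonzero(imputed),
            t.loc[imputed, "median_pi"],
            "o",
            mfc="white",
            mec="firebrick",
        )
    ax.set_xticks(range(len(t)), labels, rotation=60, fontsize=7)
    ax.set_ylabel("Median within-host pi")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
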