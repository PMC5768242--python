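"""Figure-style renderings of the cohort analysis (matplotlib, Agg-safe)."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import CohortAnalysis
from .spectral import LfpRecording, compute_spectrogram
from .stats import midranks

__all__ = [
    "plot_beta_vs_efficacy_panels",
    "plot_strategy_curves",
    "plot_spectrogram_grid",
]


def plot_beta_vs_efficacy_panels(
    analysis: CohortAnalysis, path: str | Path, ranked: bool = True
) -> None:
    """Per-hemisphere scatter of beta vs clinical efficacy (ranked values).

    One panel per hemisphere, Spearman rho in the title, the max-beta
    contact highlighted in black.
    """
    hemis = analysis.datasets
    rho_by_id = {c.hemisphere_id: c.rho for c in analysis.correlations}
    ncols = 5
    nrows = max(1, math.ceil(len(hemis) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.4 * ncols, 2.2 * nrows),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, h in zip(axes.flat, hemis):
        ax.set_visible(True)
        ids = list(h.contact_ids)
        x = np.array([h.beta[c].value for c in ids])
        y = np.array([h.clinical[c].efficacy for c in ids])
        if ranked:
            x, y = midranks(x), midranks(y)
        ax.scatter(x, y, s=18, color="tab:red")
        best = ids[int(np.argmax([h.beta[c].value for c in ids]))]
        i = ids.index(best)
        ax.scatter([x[i]], [y[i]], s=30, color="black", zorder=3)
        ax.set_title(f"{h.hemisphere_id}  rho={rho_by_id[h.hemisphere_id]:.2f}",
                     fontsize=8)
        ax.tick_params(labelsize=7)
    fig.supxlabel("normalized beta (rank)" if ranked else "normalized beta")
    fig.supylabel("clinical efficacy (rank)" if ranked else "efficacy (%/mA)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_strategy_curves(analysis: CohortAnalysis, path: str | Path) -> None:
    """Top-k hit-probability curves, one panel per criterion."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.4), sharey=True)
    for ax, criterion, title in zip(
        axes, ("efficacy", "tw"),
        ("highest clinical efficacy", "widest therapeutic window"),
    ):
        for key, style in (
            (f"{criterion}/random", dict(color="tab:blue", label="random")),
            (f"{criterion}/lfp/all", dict(color="tab:red", label="LFP (all)")),
            (f"{criterion}/lfp/beta_peak_only",
             dict(color="tab:red", linestyle="--", label="LFP (beta peak)")),
        ):
            if key not in analysis.curves:
                continue
            c = analysis.curves[key]
            ax.plot(c.k_values, c.probability, marker="o", markersize=3, **style)
        ax.set_xlabel("contacts screened (k)")
        ax.set_title(title, fontsize=9)
        ax.set_ylim(0, 1.05)
        ax.grid(alpha=0.3)
    axes[0].set_ylabel("probability best contact found")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrogram_grid(
    rec: LfpRecording, path: str | Path, fmax: float = 45.0,
    win_s: float = 1.0, step_s: float = 0.5,
) -> None:
    """Time-frequency power per contact with the beta band marked."""
    maps = compute_spectrogram(rec, win_s=win_s, step_s=step_s)
    ids = list(rec.channel_ids)
    fig, axes = plt.subplots(2, 3, figsize=(10, 5), sharex=True, sharey=True)
    for ax, cid in zip(axes.flat, ids):
        freqs, times, sxx = maps[cid]
        keep = freqs <= fmax
        ax.pcolormesh(times, freqs[keep],
                      10 * np.log10(sxx[keep] + 1e-12), shading="auto")
        for f in (13, 35):
            ax.axhline(f, color="white", linestyle="--", linewidth=0.7)
        ax.set_title(f"contact {cid}", fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("time (s)")
    for ax in axes[:, 0]:
        ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
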