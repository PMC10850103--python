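"""Minimal matplotlib renderers for coverage profiles and divergence logos.

Logos are drawn directly with stacked text glyphs scaled to the signed
letter heights; positive letters (enriched in the foreground matrix) grow
upward, negative ones downward.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .product_analysis import CoverageProfile, LogoMatrix, ResidueProfile

__all__ = ["plot_coverage", "plot_logo", "plot_residue_profile"]


def plot_coverage(profile: CoverageProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 2.5))
    x = np.arange(1, profile.smoothed.size + 1)
    ax.plot(x, profile.scaled, color="0.7", lw=0.8, label="scaled")
    ax.plot(x, profile.smoothed, color="C0", lw=1.5, label="smoothed")
    ax.set_xlabel("substrate residue")
    ax.set_ylabel("coverage")
    ax.set_title(profile.substrate_id)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_residue_profile(profile: ResidueProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 2.5))
    x = np.arange(1, profile.values.size + 1)
    ax.bar(x, profile.values, width=1.0, color="C0")
    ax.set_xlabel("substrate residue")
    ax.set_ylabel(f"{profile.kind} (%)")
    ax.set_title(profile.substrate_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_logo(logo: LogoMatrix, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(0.6 * len(logo.heights) + 1, 3))
    for col_idx, col in enumerate(logo.letter_heights.columns):
        heights = logo.letter_heights[col]
        pos = heights[heights > 0].sort_values()
        neg = heights[heights < 0].sort_values(ascending=False)
        y = 0.0
        for aa, h in pos.items():
            ax.text(col_idx, y + h / 2, aa, ha="center", va="center",
                    fontsize=6 + 60 * min(abs(h), 0.5), color="C0")
            y += h
        y = 0.0
        for aa, h in neg.items():
            ax.text(col_idx, y + h / 2, aa, ha="center", va="center",
                    fontsize=6 + 60 * min(abs(h), 0.5), color="C3")
            y += h
    lim = max(float(np.abs(logo.letter_heights.to_numpy()).sum(axis=0).max()), 0.1)
    ax.set_ylim(-lim, lim)
    ax.set_xlim(-0.5, len(logo.heights) - 0.5)
    ax.set_xticks(range(len(logo.heights)))
    ax.set_xticklabels(logo.heights.index, fontsize=8)
    ax.axhline(0, color="0.3", lw=0.8)
    ax.set_ylabel("JS divergence (bits)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
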