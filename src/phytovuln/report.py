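"""Summary plots for a pipeline run (category breakdown, vulnerability maps,
family bars).  All figures are plain matplotlib; cartographic styling is out
of scope."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .vulnerability import CATEGORIES, VulnerabilityMap

_CATEGORY_COLORS = {
    "LC": "#4daf4a", "VU": "#ffd92f", "EN": "#ff7f00", "CR": "#e41a1c", "EX": "#555555",
}


def plot_category_breakdown(counts: pd.DataFrame, path: str) -> None:
    """Stacked per-scenario bars of IUCN category percentages."""
    totals = counts.sum(axis=1)
    pct = 100.0 * counts.div(totals, axis=0)
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(pct))
    for cat in CATEGORIES:
        if cat not in pct:
            continue
        ax.bar(pct.index, pct[cat], bottom=bottom, label=cat,
               color=_CATEGORY_COLORS[cat])
        bottom += pct[cat].to_numpy()
    ax.set_ylabel("% of modeled species")
    ax.set_ylim(0, 100)
    ax.legend(title="IUCN A3", bbox_to_anchor=(1.02, 1), loc="upper left")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vulnerability_map(vuln: VulnerabilityMap, path: str, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vuln.relative_vulnerability, vmin=0, vmax=1, cmap="magma")
    fig.colorbar(im, ax=ax, label="relative vulnerability")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_family_bars(family_table: pd.DataFrame, path: str, max_families: int = 30) -> None:
    tab = family_table.head(max_families)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(tab))))
    ax.barh(tab.index.astype(str)[::-1], tab["percent_threatened"][::-1], color="#a63603")
    ax.set_xlabel("% threatened species")
    ax.set_xlim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
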