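"""Static figures: background distance distribution, module-vs-background
overlays, and a 3D scatter of the genome model.

All plotting uses the non-interactive Agg backend; functions return the
binned data they drew so tests can assert on numbers rather than pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import ParameterError
from .distances import DistanceDistribution
from .io import GeneList
from .mapping import CoordinateTable

BACKGROUND_COLOR = "#9ecae1"   # light blue
CDF_COLOR = "#08519c"          # dark blue
MODULE_COLOR = "#fa9fb5"       # pink


def plot_background(dist: DistanceDistribution, out: str | Path) -> dict:
    """Density histogram of all pairwise distances with the CDF overlaid on
    a secondary axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(dist.bin_edges)
    ax.bar(dist.bin_edges[:-1], dist.density, width=widths, align="edge",
           color=BACKGROUND_COLOR, edgecolor="none", label="all distances")
    ax.set_xlabel("pairwise Euclidean distance (model units)")
    ax.set_ylabel("density")
    ax2 = ax.twinx()
    ax2.plot(dist.bin_edges, dist.cdf, color=CDF_COLOR, lw=1.5, label="CDF")
    ax2.set_ylabel("cumulative probability")
    ax2.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return {"density": dist.density, "cdf": dist.cdf, "bin_edges": dist.bin_edges}


def plot_module_overlay(sample: np.ndarray, background: DistanceDistribution,
                        out: str | Path, label: str = "module",
                        ks: float | None = None,
                        pval_adjusted: float | None = None) -> dict:
    """Normalized module histogram (pink) over the background histogram
    (light blue), using the background's bin edges; annotates D and the
    adjusted p when given."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) == 0:
        raise ParameterError("empty module distance sample")
    if background.source_count == 0:
        raise ParameterError("empty background distribution")
    edges = background.bin_edges
    counts, _ = np.histogram(sample, bins=edges)
    width = edges[1] - edges[0]
    sample_density = counts / (counts.sum() * width)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], background.density, width=np.diff(edges), align="edge",
           color=BACKGROUND_COLOR, label="all distances")
    ax.bar(edges[:-1], sample_density, width=np.diff(edges), align="edge",
           color=MODULE_COLOR, alpha=0.7, label=label)
    note = []
    if ks is not None:
        note.append(f"D = {ks:.3f}")
    if pval_adjusted is not None:
        note.append(f"adj. p = {pval_adjusted:.2g}")
    if note:
        ax.set_title(f"{label}: " + ", ".join(note))
    ax.set_xlabel("pairwise Euclidean distance (model units)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return {"bin_edges": edges, "sample_density": sample_density,
            "background_density": background.density}


def plot_genome3d(coords: CoordinateTable, out: str | Path,
                  highlight: GeneList | None = None) -> dict:
    """Static 3D scatter of mapped features, colour-coded by chromosome,
    with highlighted genes emphasized."""
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    df = coords.records
    chroms = list(dict.fromkeys(df["chromosome"]))
    cmap = plt.get_cmap("tab20")
    for i, chrom in enumerate(chroms):
        sub = df[df["chromosome"] == chrom]
        ax.scatter(sub["x"], sub["y"], sub["z"], s=3, alpha=0.5,
                   color=cmap(i % 20), label=chrom)
    n_highlight = 0
    if highlight is not None:
        wanted = set(highlight.ids)
        sub = df[df["feature_id"].isin(wanted)]
        n_highlight = len(sub)
        ax.scatter(sub["x"], sub["y"], sub["z"], s=40, color="red",
                   edgecolor="black", depthshade=False, label=highlight.label)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return {"n_points": len(df), "n_chromosomes": len(chroms),
            "n_highlighted": n_highlight}
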