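"""Static figure analogues: distance-density panels, CN composition
heatmaps, SC-map graphs and barycentric triangles.  PNG + SVG output with
date metadata stripped so reruns are byte-stable."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .neighborhoods import NeighbourhoodModel
from .spatial_context import _TRIANGLE, BarycentricProjection


def _save(fig, stem: Path) -> None:
    stem.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(stem.with_suffix(".png"), dpi=120)
    fig.savefig(stem.with_suffix(".svg"), metadata={"Date": None})
    plt.close(fig)


def distance_profile_panels(profiles: pd.DataFrame, stem,
                            group_col: str = "response_group",
                            hue_col: str = "ispla_positive") -> None:
    """Small multiples of normalised signed-distance histograms; negative
    distances lie inside the tumour."""
    groups = sorted(profiles[group_col].unique())
    fig, axes = plt.subplots(1, max(len(groups), 1),
                             figsize=(4 * max(len(groups), 1), 3),
                             sharey=True, squeeze=False)
    for ax, g in zip(axes[0], groups):
        sub = profiles[profiles[group_col] == g]
        for hue, h in sub.groupby(hue_col):
            ax.step(h["bin_left"], h["density"], where="post",
                    label=f"{hue_col}={hue}")
        ax.axvline(0, color="k", lw=0.8, ls="--")
        ax.set_title(str(g))
        ax.set_xlabel("distance to tumour boundary (µm)")
    axes[0][0].set_ylabel("normalised cell count")
    if len(groups):
        axes[0][-1].legend(fontsize=7)
    _save(fig, Path(stem))


def cn_composition_heatmap(model: NeighbourhoodModel, stem) -> None:
    """CN centroid compositions: neighbourhoods x label alphabet."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(model.alphabet),
                                    1 + 0.4 * model.K))
    im = ax.imshow(model.centroids, aspect="auto", cmap="viridis",
                   vmin=0, vmax=model.centroids.max())
    ax.set_xticks(range(len(model.alphabet)))
    ax.set_xticklabels(model.alphabet, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(model.K))
    ax.set_yticklabels([f"CN{j}" for j in range(model.K)], fontsize=7)
    fig.colorbar(im, ax=ax, label="frequency")
    ax.set_title(f"CN composition ({model.variant}, K={model.K})", fontsize=9)
    _save(fig, Path(stem))


def inertia_curve_plot(model: NeighbourhoodModel, stem) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ks = sorted(model.inertia_curve)
    ax.plot(ks, [model.inertia_curve[k] for k in ks], "o-")
    ax.axvline(model.selected_K, color="r", ls="--",
               label=f"elbow K={model.selected_K}")
    ax.set_xlabel("K")
    ax.set_ylabel("inertia")
    ax.legend()
    _save(fig, Path(stem))


def scm_graph_plot(g: nx.DiGraph, stem, title: str = "") -> None:
    """SC map: combination nodes layered by size, node area ~ cell fraction."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(g):
        layers: Dict[int, list] = {}
        for node, data in g.nodes(data=True):
            layers.setdefault(data["size"], []).append(node)
        pos = {}
        for size, nodes in sorted(layers.items()):
            for i, node in enumerate(sorted(nodes)):
                pos[node] = (i - (len(nodes) - 1) / 2.0, -size)
        sizes = [3000 * g.nodes[n]["fraction"] + 30 for n in g.nodes]
        nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, font_size=6,
                         node_color="#87b5d6", arrows=True, width=0.6)
    ax.set_title(title, fontsize=9)
    ax.axis("off")
    _save(fig, Path(stem))


def barycentric_plot(proj: BarycentricProjection, stem,
                     cn_col: str = "cn_label_pla", title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    tri = np.vstack([_TRIANGLE, _TRIANGLE[:1]])
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
    for j, cid in enumerate(proj.triple):
        ax.annotate(f"CN{cid}", _TRIANGLE[j], fontsize=8,
                    ha="center", va="bottom")
    if len(proj.df):
        for cn, sub in proj.df.groupby(cn_col):
            ax.scatter(sub["u"], sub["v"], s=3, alpha=0.5, label=f"CN{cn}")
        ax.legend(fontsize=6, markerscale=2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)
    _save(fig, Path(stem))
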