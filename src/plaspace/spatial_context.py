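"""Spatial contexts (SCs), SC maps and barycentric interface projections.

A cell's spatial context is the *minimal combination* of cellular
neighbourhoods (CNs) that together account for more than 90% of its large
window (its 100 nearest neighbours): CNs are added in decreasing abundance
until the cumulative frequency exceeds the threshold.  Combinations are
identified as id-sorted tuples.  Per response group, the SC map (SCM) is a
directed graph over combinations above a minimum cell fraction, with edges
from each combination to its one-larger supersets.  Interfaces between
three chosen CNs are visualised by projecting near-pure windows (>= 99.95%
mass on the triple) into barycentric coordinates of a reference triangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CellTable
from .neighborhoods import knn_windows, window_composition

__all__ = ["minimal_combination", "sc_windows", "assign_spatial_context",
           "build_scm_graph", "scm_graphs_by_group", "barycentric_projection",
           "combination_key", "tumour_macrophage_interface_fraction"]


def sc_windows(table: CellTable, k: int = 100, cn_col: str = "cn_label_pla",
               n_cn: Optional[int] = None, include_self: bool = True
               ) -> np.ndarray:
    """CN-frequency vectors over each cell's large spatial window."""
    if cn_col not in table.df.columns:
        raise ValueError(f"missing CN labels: {cn_col!r}")
    labels = table.df[cn_col].to_numpy()
    if n_cn is None:
        n_cn = int(labels.max()) + 1
    win = knn_windows(table.xy, k, include_self=include_self)
    return window_composition(win, [int(l) for l in labels], list(range(n_cn)))


def minimal_combination(freq: np.ndarray, threshold: float = 0.90
                        ) -> Tuple[int, ...]:
    """Shortest abundance-ordered CN prefix whose cumulative frequency
    strictly exceeds ``threshold``; returned sorted by CN id.

    Abundance ties are broken by ascending CN id.
    """
    freq = np.asarray(freq, float)
    if freq.sum() <= 0:
        raise ValueError("all-zero frequency vector")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ids = np.arange(len(freq))
    order = np.lexsort((ids, -freq))          # desc frequency, asc id
    cum = np.cumsum(freq[order])
    stop = int(np.argmax(cum > threshold))
    if cum[stop] <= threshold:                # numerical tail guard
        stop = len(freq) - 1
    return tuple(sorted(int(i) for i in order[:stop + 1]))


def combination_key(comb: Tuple[int, ...]) -> str:
    return "+".join(str(c) for c in comb)


def assign_spatial_context(table: CellTable, cfg: PipelineConfig,
                           cn_col: str = "cn_label_pla",
                           n_cn: Optional[int] = None
                           ) -> Tuple[CellTable, np.ndarray]:
    """Write per-cell minimal CN combinations (``sc_combination`` column,
    id-sorted '+'-joined string); also return the window frequency matrix
    for reuse by the barycentric projection."""
    freqs = sc_windows(table, k=cfg.sc_window_k, cn_col=cn_col, n_cn=n_cn,
                       include_self=cfg.include_index_cell)
    combos = [combination_key(minimal_combination(f, cfg.sc_threshold))
              for f in freqs]
    return table.with_column("sc_combination", np.asarray(combos, object)), freqs


def build_scm_graph(combinations: Sequence[str],
                    min_fraction: float = 1e-5) -> nx.DiGraph:
    """SC map: nodes are combinations above the cell-fraction floor; each
    edge links a combination to a superset exactly one CN larger.

    Edges always point from the simpler to the more complex combination,
    so the graph is a DAG by construction.
    """
    combos = pd.Series(list(combinations))
    n_total = len(combos)
    if n_total == 0:
        return nx.DiGraph()
    counts = combos.value_counts()
    g = nx.DiGraph()
    kept = {}
    for key, cnt in counts.items():
        frac = cnt / n_total
        if frac > min_fraction:
            members = tuple(int(x) for x in key.split("+"))
            g.add_node(key, count=int(cnt), fraction=float(frac),
                       size=len(members))
            kept[key] = frozenset(members)
    for k1, s1 in kept.items():
        for k2, s2 in kept.items():
            if len(s2) == len(s1) + 1 and s1 < s2:
                g.add_edge(k1, k2)
    return g


def scm_graphs_by_group(tables: Sequence[CellTable], groups: Dict[str, str],
                        min_fraction: float = 1e-5) -> Dict[str, nx.DiGraph]:
    """One SC map per response group, pooling that group's cells."""
    by_group: Dict[str, List[str]] = {}
    for t in tables:
        if "sc_combination" not in t.df.columns:
            raise ValueError("assign_spatial_context has not run")
        g = groups[t.sample_id]
        by_group.setdefault(g, []).extend(t.df["sc_combination"].tolist())
    return {g: build_scm_graph(c, min_fraction) for g, c in by_group.items()}


def tumour_macrophage_interface_fraction(combinations: Sequence[str],
                                         model) -> float:
    """Fraction of cells whose spatial context joins the tumour-dominated
    CN with at least one macrophage-led CN.

    This is the SC-map signature of a peritumoural macrophage barrier:
    large windows in which tumour and macrophage neighbourhoods interface
    directly.  Implemented as combination *membership* (contains the
    tumour CN and >= 1 CN whose top centroid component is Macrophage)
    rather than one exact pair, because the band may split across several
    macrophage CNs at larger K.
    """
    alphabet = model.alphabet
    tum_mass = np.array([sum(c[j] for j, lab in enumerate(alphabet)
                             if lab.startswith("Tumour"))
                         for c in model.centroids])
    tum_cn = int(np.argmax(tum_mass))
    mac_cns = {i for i, c in enumerate(model.centroids)
               if alphabet[int(np.argmax(c))].startswith("Macrophage")}
    if not combinations:
        return float("nan")
    hits = 0
    for key in combinations:
        members = {int(x) for x in key.split("+")}
        if tum_cn in members and members & mac_cns:
            hits += 1
    return hits / len(combinations)


#: Equilateral reference triangle with unit side, base on the x-axis.
_TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass
class BarycentricProjection:
    triple: Tuple[int, int, int]
    purity: float
    df: pd.DataFrame              # cell_id, u, v, cn_label, weights w0..w2
    flagged: bool = False         # no qualifying windows


def barycentric_projection(freqs: np.ndarray, table: CellTable,
                           triple: Tuple[int, int, int],
                           purity: float = 0.9995,
                           cn_col: str = "cn_label_pla"
                           ) -> BarycentricProjection:
    """Project near-pure windows of a CN triple into the reference triangle.

    Windows whose mass on the triple is >= ``purity`` are kept; their three
    frequencies are renormalised to barycentric weights and mapped to the
    triangle's plane.  Cells are carried with their own CN label for
    colouring (vertices = pure CNs, edges = pairwise interfaces).
    """
    triple = tuple(int(t) for t in triple)
    if len(set(triple)) != 3:
        raise ValueError("triple must contain three distinct CN ids")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    f3 = freqs[:, list(triple)]
    mass = f3.sum(axis=1)
    keep = mass >= purity
    if not keep.any():
        return BarycentricProjection(triple, purity,
                                     pd.DataFrame(columns=["cell_id", "u", "v",
                                                           cn_col, "w0", "w1",
                                                           "w2"]),
                                     flagged=True)
    w = f3[keep] / mass[keep, None]
    uv = w @ _TRIANGLE
    df = pd.DataFrame({
        "cell_id": table.df.loc[keep, "cell_id"].to_numpy(),
        "u": uv[:, 0], "v": uv[:, 1],
        cn_col: table.df.loc[keep, cn_col].to_numpy(),
        "w0": w[:, 0], "w1": w[:, 1], "w2": w[:, 2],
    })
    return BarycentricProjection(triple, purity, df, flagged=False)
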