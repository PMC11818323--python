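"""Cellular-neighbourhood (CN) discovery.

Each cell is summarised by the cell-type composition of its spatial window
(the cell plus its k nearest neighbours, k=10 by default); pooled window
compositions are clustered with KMeans over a range of K (3-15), and the
elbow of the inertia curve -- located with the Kneedle rule -- selects the
number of neighbourhoods.  Two variants are fitted: the plain cell-type
alphabet, and the alphabet refined by isPLA positivity (type x +/-), which
separates e.g. "tumour & immune, PLA+" from "tumour, PLA-" neighbourhoods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .core import CELL_TYPES, CellTable

__all__ = ["knn_windows", "window_composition", "fit_cn", "select_k_kneedle",
           "NeighbourhoodModel", "fit_neighbourhoods", "assign_cn",
           "augmented_labels", "augmented_alphabet"]


def knn_windows(xy: np.ndarray, k: int, include_self: bool = True
                ) -> np.ndarray:
    """Spatial k-NN windows: row i lists cell i's window member indices.

    Neighbours are the k nearest *other* cells (Euclidean); distance ties
    are broken by ascending cell index.  With ``include_self`` the window
    is the cell plus its neighbours (size k+1), the convention used for
    CN windows.
    """
    xy = np.asarray(xy, float)
    n = len(xy)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    # query a few extra neighbours so index-order tie-breaking is stable
    # even when coordinates are duplicated
    q = min(k + 6, n)
    nn = NearestNeighbors(n_neighbors=q).fit(xy)
    dist, idx = nn.kneighbors(xy)
    rows = np.empty((n, k + 1 if include_self else k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx[i], np.round(dist[i], 9)))
        cand = idx[i][order]
        neigh = cand[cand != i][:k]
        rows[i] = np.concatenate(([i], neigh)) if include_self else neigh
    return rows


def window_composition(windows: np.ndarray, labels: Sequence,
                       alphabet: Sequence) -> np.ndarray:
    """Per-window label-frequency matrix over a fixed alphabet.

    Rows sum to 1; raises if a label falls outside the alphabet.
    """
    alphabet = list(alphabet)
    lut = {lab: j for j, lab in enumerate(alphabet)}
    labels = np.asarray(labels, dtype=object)
    unknown = set(labels) - set(alphabet)
    if unknown:
        raise ValueError(f"labels outside alphabet: {sorted(map(str, unknown))}")
    codes = np.array([lut[l] for l in labels], dtype=np.int64)
    n, w = windows.shape
    comp = np.zeros((n, len(alphabet)))
    np.add.at(comp, (np.repeat(np.arange(n), w), codes[windows].ravel()), 1.0)
    return comp / w


def fit_cn(comp: np.ndarray, K: int, seed: int = 0, n_restarts: int = 10
           ) -> Tuple[np.ndarray, np.ndarray, float]:
    """KMeans (k-means++ / Lloyd, best of ``n_restarts``) on compositions.

    Returns (centroids, labels, inertia); deterministic for a fixed seed.
    """
    if K < 1 or K > len(comp):
        raise ValueError("K must satisfy 1 <= K <= n_rows")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(comp)
    return km.cluster_centers_, km.labels_.astype(int), float(km.inertia_)


def select_k_kneedle(inertia_curve: Dict[int, float]) -> int:
    """Kneedle elbow of a decreasing inertia curve.

    Min-max normalise K and inertia, invert the (decreasing) y so the curve
    rises, and take the K maximising the difference to the diagonal
    (sensitivity 1).  The argmax must be a local maximum of the difference
    curve; otherwise fall back to the point of maximum discrete curvature,
    and for a flat curve return the smallest K.
    """
    ks = np.array(sorted(inertia_curve))
    ys = np.array([inertia_curve[k] for k in ks], float)
    if len(ks) < 3:
        return int(ks[0])
    if ys[-1] > ys[0]:
        raise ValueError("curve is increasing; not an inertia curve")
    if np.ptp(ys) == 0:
        return int(ks[0])                      # flat: degenerate fallback
    x_n = (ks - ks[0]) / (ks[-1] - ks[0])
    y_n = (ys - ys.min()) / np.ptp(ys)
    diff = (1.0 - y_n) - x_n
    best = int(np.argmax(diff))
    is_local_max = ((best == 0 or diff[best] >= diff[best - 1]) and
                    (best == len(diff) - 1 or diff[best] >= diff[best + 1]))
    interior = 0 < best < len(diff) - 1
    if interior and is_local_max:
        return int(ks[best])
    # no interior knee: maximum discrete curvature of the normalised curve
    curv = np.abs(np.diff(y_n, 2))
    if curv.size == 0 or np.ptp(curv) == 0:
        return int(ks[0])
    return int(ks[int(np.argmax(curv)) + 1])


def augmented_labels(df: pd.DataFrame) -> np.ndarray:
    """Cell-type labels refined by isPLA state, e.g. 'Macrophage PLA+'."""
    sign = np.where(df["ispla_positive"].to_numpy(bool), "PLA+", "PLA-")
    return np.char.add(np.char.add(df["cell_type"].to_numpy(str), " "), sign
                       ).astype(object)


def augmented_alphabet(types: Sequence[str] = CELL_TYPES) -> List[str]:
    return [f"{t} {s}" for t in types for s in ("PLA-", "PLA+")]


@dataclass
class NeighbourhoodModel:
    """Fitted CN model: centroids in composition space plus the K-selection
    trace."""

    variant: str                       # "plain" | "ispla_augmented"
    alphabet: List[str]
    window_k: int
    include_self: bool
    centroids: np.ndarray
    inertia_curve: Dict[int, float]
    selected_K: int
    seed: int

    @property
    def K(self) -> int:
        return len(self.centroids)

    def predict(self, comp: np.ndarray) -> np.ndarray:
        return np.argmin(cdist(comp, self.centroids), axis=1)

    def cn_names(self, top: int = 2) -> List[str]:
        """Display names from dominant centroid components."""
        names = []
        for c in self.centroids:
            order = np.argsort(-c)
            parts = [f"{self.alphabet[j]} {c[j]:.0%}"
                     for j in order[:top] if c[j] >= 0.15]
            names.append(" / ".join(parts) if parts else self.alphabet[order[0]])
        return names

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant, "alphabet": self.alphabet,
            "window_k": self.window_k, "include_self": self.include_self,
            "centroids": self.centroids.tolist(),
            "inertia_curve": {str(k): v for k, v in self.inertia_curve.items()},
            "selected_K": self.selected_K, "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NeighbourhoodModel":
        d = json.loads(text)
        return cls(variant=d["variant"], alphabet=d["alphabet"],
                   window_k=d["window_k"], include_self=d["include_self"],
                   centroids=np.asarray(d["centroids"]),
                   inertia_curve={int(k): v
                                  for k, v in d["inertia_curve"].items()},
                   selected_K=d["selected_K"], seed=d["seed"])


def _cohort_compositions(tables: Sequence[CellTable], alphabet: List[str],
                         window_k: int, include_self: bool, variant: str
                         ) -> np.ndarray:
    """Windows never cross sample boundaries; compositions are pooled."""
    comps = []
    for t in tables:
        labels = (augmented_labels(t.df) if variant == "ispla_augmented"
                  else t.df["cell_type"].to_numpy(object))
        win = knn_windows(t.xy, window_k, include_self=include_self)
        comps.append(window_composition(win, labels, alphabet))
    return np.concatenate(comps)


def fit_neighbourhoods(tables: Sequence[CellTable], cfg: PipelineConfig,
                       variant: str = "plain",
                       K: Optional[int] = None) -> NeighbourhoodModel:
    """Fit a CN model on window compositions pooled across the cohort.

    Pooling gives one shared CN vocabulary for all samples and response
    groups.  ``K=None`` scans ``cfg.cn_k_range`` and selects the inertia
    elbow with the Kneedle rule.
    """
    if variant not in ("plain", "ispla_augmented"):
        raise ValueError(f"unknown variant: {variant!r}")
    alphabet = (augmented_alphabet() if variant == "ispla_augmented"
                else list(CELL_TYPES))
    comp = _cohort_compositions(tables, alphabet, cfg.cn_window_k,
                                cfg.include_index_cell, variant)
    lo, hi = cfg.cn_k_range
    curve: Dict[int, float] = {}
    for k in range(lo, hi + 1):
        _, _, inertia = fit_cn(comp, k, seed=cfg.random_seed,
                               n_restarts=cfg.cn_restarts)
        curve[k] = inertia
    selected = K if K is not None else select_k_kneedle(curve)
    centroids, _, _ = fit_cn(comp, selected, seed=cfg.random_seed,
                             n_restarts=cfg.cn_restarts)
    return NeighbourhoodModel(variant=variant, alphabet=alphabet,
                              window_k=cfg.cn_window_k,
                              include_self=cfg.include_index_cell,
                              centroids=centroids, inertia_curve=curve,
                              selected_K=selected, seed=cfg.random_seed)


def assign_cn(model: NeighbourhoodModel, table: CellTable) -> CellTable:
    """Label each cell with its nearest CN centroid.

    Writes ``cn_label`` (plain variant) or ``cn_label_pla`` (augmented).
    """
    labels = (augmented_labels(table.df) if model.variant == "ispla_augmented"
              else table.df["cell_type"].to_numpy(object))
    unknown = set(labels) - set(model.alphabet)
    if unknown:
        raise ValueError(
            f"table labels outside model alphabet: {sorted(map(str, unknown))}")
    win = knn_windows(table.xy, model.window_k,
                      include_self=model.include_self)
    comp = window_composition(win, labels, model.alphabet)
    col = "cn_label" if model.variant == "plain" else "cn_label_pla"
    return table.with_column(col, model.predict(comp))
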