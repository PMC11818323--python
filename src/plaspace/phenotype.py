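"""QC, expression preprocessing and phenotyping.

Mirrors the published cell-classification protocol: nuclei outside the
10-220 µm² window (or with dim DAPI) are discarded as segmentation
artefacts; the six marker intensities plus nuclear area are arcsinh
transformed (cofactor 150), z-scored first within columns and then across
rows, clustered on a k-nearest-neighbour graph with Leiden community
detection (k=30, resolution 2), and the clusters are annotated into the
five cell types by their dominant canonical marker (PanCK -> Tumour,
CD20 -> B cell, CD68 -> Macrophage, CD8 -> CD8 T cell, CD3e -> CD3 T cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .core import MARKERS, CellTable

#: Canonical marker -> cell type, in tie-break precedence order.
CANONICAL = [
    ("PanCK", "Tumour"),
    ("CD20", "B cell"),
    ("CD68", "Macrophage"),
    ("CD8", "CD8 T cell"),
    ("CD3e", "CD3 T cell"),
]

FEATURES = MARKERS + ["nuclear_area"]

_TIE_MARGIN = 1e-6


@dataclass
class QCReport:
    n_input: int
    n_removed_small: int
    n_removed_large: int
    n_removed_dapi: int

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_removed_small - self.n_removed_large
                - self.n_removed_dapi)


def qc_filter(table: CellTable, cfg: PipelineConfig
              ) -> Tuple[CellTable, QCReport]:
    """Drop segmentation artefacts; the area window is closed on both ends.

    Removal reasons are counted sequentially (small area, then large area,
    then dim DAPI) so the report totals the input size.
    """
    df = table.df
    area = df["nuclear_area"].to_numpy(float)
    dapi = df["DAPI"].to_numpy(float)
    small = area < cfg.qc_min_area
    large = ~small & (area > cfg.qc_max_area)
    dim = ~small & ~large & (dapi < cfg.qc_min_dapi)
    keep = ~(small | large | dim)
    report = QCReport(n_input=len(df),
                      n_removed_small=int(small.sum()),
                      n_removed_large=int(large.sum()),
                      n_removed_dapi=int(dim.sum()))
    if report.n_retained == 0:
        import warnings
        warnings.warn(f"QC removed every cell of sample {table.sample_id!r}")
    out = CellTable(table.sample_id, df.loc[keep].reset_index(drop=True))
    return out, report


@dataclass
class ExpressionMatrix:
    """Cells x features matrix with an explicit preprocessing stage flag."""

    data: pd.DataFrame            # index: sample_id + cell_id MultiIndex
    stage: str                    # "raw" | "arcsinh" | "scaled"

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "arcsinh", "scaled"):
            raise ValueError(f"unknown stage: {self.stage!r}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


def expression_matrix(tables: Sequence[CellTable],
                      include_area: bool = True) -> ExpressionMatrix:
    """Assemble the raw feature matrix (6 markers + nuclear area) from one
    or more QC-passed cell tables."""
    frames = []
    cols = MARKERS + (["nuclear_area"] if include_area else [])
    for t in tables:
        sub = t.df[cols].copy()
        sub.index = pd.MultiIndex.from_arrays(
            [np.full(len(sub), t.sample_id), t.df["cell_id"].to_numpy()],
            names=["sample_id", "cell_id"])
        frames.append(sub)
    return ExpressionMatrix(pd.concat(frames), stage="raw")


def arcsinh_transform(m: ExpressionMatrix, cofactor: float = 150.0,
                      transform_area: bool = True) -> ExpressionMatrix:
    """x -> asinh(x / cofactor), elementwise.

    Variance-stabilises fluorescence intensities: linear near zero,
    logarithmic for bright signal.  Nuclear area passes through the same
    transform by default (it is one clustering feature among seven); set
    ``transform_area=False`` to append it raw.
    """
    if m.stage != "raw":
        raise ValueError(f"arcsinh_transform expects stage 'raw', got {m.stage!r}")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = m.data.copy()
    cols = list(out.columns)
    if not transform_area and "nuclear_area" in cols:
        cols.remove("nuclear_area")
    out[cols] = np.arcsinh(out[cols].to_numpy(float) / cofactor)
    return ExpressionMatrix(out, stage="arcsinh")


def _scale_axis(x: np.ndarray, axis: int, how: str) -> np.ndarray:
    if how == "zscore":
        mu = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        return np.where(sd == 0, 0.0, z)   # constant slice -> zeros
    if how == "minmax":
        lo = x.min(axis=axis, keepdims=True)
        hi = x.max(axis=axis, keepdims=True)
        rng = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - lo) / rng
        return np.where(rng == 0, 0.0, z)
    raise ValueError(f"unknown scaling: {how!r}")


def dual_scale(m: ExpressionMatrix, how: str = "zscore") -> ExpressionMatrix:
    """Scale within columns (markers) and then across rows (cells).

    Pass 1 standardises each feature over the cohort; pass 2 standardises
    each cell's profile, emphasising its *relative* marker pattern.
    Zero-variance slices map to zeros rather than NaN.
    """
    if m.stage != "arcsinh":
        raise ValueError(f"dual_scale expects stage 'arcsinh', got {m.stage!r}")
    x = m.values
    x = _scale_axis(x, axis=0, how=how)
    x = _scale_axis(x, axis=1, how="zscore")
    return ExpressionMatrix(pd.DataFrame(x, index=m.data.index,
                                         columns=m.data.columns),
                            stage="scaled")


def _knn_edges(x: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """Undirected k-NN edge list; neighbour ties broken by cell index."""
    n = len(x)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(x)
    dist, idx = nn.kneighbors(x)
    edges = set()
    for i in range(n):
        # stable order: distance, then index; drop self
        order = np.lexsort((idx[i], np.round(dist[i], 12)))
        neigh = [j for j in idx[i][order] if j != i][:k]
        for j in neigh:
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def cluster_cells(m: ExpressionMatrix, k: int = 30, resolution: float = 2.0,
                  seed: int = 0) -> np.ndarray:
    """Leiden community detection on the Euclidean k-NN graph.

    Returns dense integer labels 0..C-1.  Deterministic for a fixed seed.
    """
    if m.stage != "scaled":
        raise ValueError("cluster_cells expects a scaled matrix")
    x = m.values
    n = len(x)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    if np.all(x == x[0]):
        return np.zeros(n, dtype=int)   # zero-distance graph: one community
    edges = _knn_edges(x, k)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2)
    return np.asarray(part.membership, dtype=int)


@dataclass
class PhenotypeResult:
    cluster: np.ndarray           # per-cell cluster id
    cell_type: np.ndarray         # per-cell annotated type
    annotation: pd.DataFrame      # per-cluster mean canonical-marker values,
                                  # z-scores and assigned type


def annotate_clusters(labels: np.ndarray, m_arcsinh: ExpressionMatrix
                      ) -> PhenotypeResult:
    """Assign each cluster the type of its most-enriched canonical marker.

    Enrichment is the z-score of the cluster mean against the grand mean
    (grand SD units) on the arcsinh scale.  Ties below a 1e-6 margin fall
    back on the fixed precedence PanCK > CD20 > CD68 > CD8 > CD3e.
    """
    if m_arcsinh.stage != "arcsinh":
        raise ValueError("annotate_clusters expects the arcsinh matrix")
    labels = np.asarray(labels)
    if len(labels) != len(m_arcsinh.data):
        raise ValueError("labels do not cover the matrix rows")
    markers = [mk for mk, _ in CANONICAL]
    x = m_arcsinh.data[markers].to_numpy(float)
    grand_mu = x.mean(axis=0)
    grand_sd = x.std(axis=0)
    grand_sd = np.where(grand_sd == 0, 1.0, grand_sd)

    rows = []
    cluster_type: Dict[int, str] = {}
    for c in np.unique(labels):
        mu = x[labels == c].mean(axis=0)
        z = (mu - grand_mu) / grand_sd
        best = int(np.argmax(z))
        # precedence-ordered tie resolution
        for j in range(len(markers)):
            if z[j] >= z[best] - _TIE_MARGIN:
                best = j
                break
        cluster_type[int(c)] = CANONICAL[best][1]
        row = {"cluster": int(c), "n": int((labels == c).sum()),
               "cell_type": CANONICAL[best][1]}
        row.update({f"mean_{mk}": mu[j] for j, mk in enumerate(markers)})
        row.update({f"z_{mk}": z[j] for j, mk in enumerate(markers)})
        rows.append(row)
    ann = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    cell_type = np.array([cluster_type[int(c)] for c in labels], dtype=object)
    return PhenotypeResult(cluster=labels, cell_type=cell_type, annotation=ann)


def phenotype_cells(tables: Sequence[CellTable], cfg: PipelineConfig
                    ) -> Tuple[List[CellTable], PhenotypeResult, List[QCReport]]:
    """End-to-end phenotyping: QC each sample, pool the cohort, transform,
    scale, cluster and annotate; write ``cluster``/``cell_type`` back onto
    per-sample tables."""
    filtered, reports = [], []
    for t in tables:
        ft, rep = qc_filter(t, cfg)
        filtered.append(ft)
        reports.append(rep)
    raw = expression_matrix(filtered)
    arc = arcsinh_transform(raw, cfg.arcsinh_cofactor,
                            transform_area=cfg.transform_area)
    scaled = dual_scale(arc, how=cfg.scaling)
    labels = cluster_cells(scaled, k=cfg.phenotype_knn_k,
                           resolution=cfg.phenotype_resolution,
                           seed=cfg.random_seed)
    result = annotate_clusters(labels, arc)

    out: List[CellTable] = []
    start = 0
    for t in filtered:
        n = len(t)
        df = t.df.copy()
        df["cluster"] = result.cluster[start:start + n]
        df["cell_type"] = result.cell_type[start:start + n]
        out.append(CellTable(t.sample_id, df))
        start += n
    return out, result, reports
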