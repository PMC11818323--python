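"""Tumour/stroma mask and signed boundary distances.

The published analysis drew its tumour mask from a pixel classifier on the
PanCK channel; working from segmented cell tables, the equivalent here is a
density mask: tumour-cell counts are rastered on a coarse grid, smoothed
with a Gaussian, thresholded, and iso-contoured into nest polygons.  Nests
at or below the minimum area (100 µm² by default) are discarded.  Signed
distances to the nearest nest boundary are negative inside a nest and
positive in stroma; a cell exactly on a boundary has distance 0 and is
labelled tumour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping
from shapely.ops import unary_union
from skimage import measure

from .config import PipelineConfig
from .core import CellTable

__all__ = ["RegionMask", "BoundaryDistanceTable", "build_tumour_mask",
           "signed_boundary_distance", "distance_density_profile",
           "mask_from_polygons"]


@dataclass
class RegionMask:
    """Tumour-nest polygon set plus per-cell tumour/stroma labels."""

    polygons: List[Polygon]
    region: pd.Series                  # index: cell_id; values tumour/stroma
    threshold: float                   # density threshold used (cells/µm²)
    grid_pitch: float

    @property
    def nest_areas(self) -> List[float]:
        return [p.area for p in self.polygons]

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0

    def to_geojson(self) -> dict:
        feats = [{"type": "Feature", "geometry": mapping(p),
                  "properties": {"nest_id": i, "area_um2": p.area}}
                 for i, p in enumerate(self.polygons)]
        return {"type": "FeatureCollection", "features": feats}


@dataclass
class BoundaryDistanceTable:
    """Per-cell signed distance (µm) to the nearest nest boundary."""

    df: pd.DataFrame                   # cell_id, distance_um, nearest_nest
    valid: bool = True                 # False when the mask was empty


def _label_cells(table: CellTable, polygons: Sequence[Polygon]) -> pd.Series:
    xy = table.xy
    if len(polygons) == 0 or len(xy) == 0:
        vals = np.full(len(xy), "stroma", dtype=object)
    else:
        union = unary_union(list(polygons))
        # intersects == covers for point-in-polygon: boundary cells are tumour
        inside = shapely.intersects_xy(union, xy[:, 0], xy[:, 1])
        vals = np.where(inside, "tumour", "stroma").astype(object)
    return pd.Series(vals, index=table.df["cell_id"].to_numpy(), name="region")


def build_tumour_mask(table: CellTable, cfg: PipelineConfig) -> RegionMask:
    """Contour the smoothed tumour-cell density into nest polygons.

    The raster origin is pinned to the data bounding box, which makes the
    mask translation-equivariant.  The default threshold is half the mean
    smoothed density over grid cells that contain at least one tumour cell;
    override via ``cfg.mask_threshold`` (cells/µm²).
    """
    if "cell_type" not in table.df.columns:
        raise ValueError("build_tumour_mask requires cell_type labels")
    pitch = cfg.mask_grid_pitch
    tumour_xy = table.df.loc[table.df["cell_type"] == "Tumour",
                             ["x", "y"]].to_numpy(float)
    if len(tumour_xy) == 0:
        warnings.warn(f"sample {table.sample_id!r}: no tumour cells; "
                      "empty mask, all cells stroma")
        return RegionMask([], _label_cells(table, []), float("nan"), pitch)

    xy = table.xy
    x0, y0 = xy[:, 0].min(), xy[:, 1].min()
    x1, y1 = xy[:, 0].max(), xy[:, 1].max()
    nx = max(int(np.ceil((x1 - x0) / pitch)), 1) + 1
    ny = max(int(np.ceil((y1 - y0) / pitch)), 1) + 1
    counts, _, _ = np.histogram2d(
        tumour_xy[:, 0], tumour_xy[:, 1], bins=[nx, ny],
        range=[[x0, x0 + nx * pitch], [y0, y0 + ny * pitch]])
    density = counts / (pitch * pitch)
    smooth = gaussian_filter(density, sigma=cfg.mask_sigma)

    if cfg.mask_threshold is not None:
        level = cfg.mask_threshold
    else:
        occupied = counts > 0
        level = 0.5 * float(smooth[occupied].mean())

    # pad with zeros so iso-contours close at the field edge
    pad = np.pad(smooth, 1, mode="constant")
    contours = measure.find_contours(pad, level)
    polys: List[Polygon] = []
    for c in contours:
        if len(c) < 4:
            continue
        # contour coords are (row=ix, col=iy) in padded bin units; a bin
        # centre (i, j) sits at x0 + (i + 0.5) * pitch
        px = x0 + (c[:, 0] - 1 + 0.5) * pitch
        py = y0 + (c[:, 1] - 1 + 0.5) * pitch
        poly = Polygon(np.column_stack([px, py]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        polys.append(poly)
    # union overlapping/nested contours, then apply the nest-area floor
    merged = unary_union(polys) if polys else None
    nests: List[Polygon] = []
    if merged is not None and not merged.is_empty:
        geoms = getattr(merged, "geoms", [merged])
        nests = [g for g in geoms
                 if isinstance(g, Polygon) and g.area > cfg.mask_min_nest_area]
    nests.sort(key=lambda p: (-p.area, p.centroid.x, p.centroid.y))
    return RegionMask(nests, _label_cells(table, nests), float(level), pitch)


def mask_from_polygons(table: CellTable, polygons: Sequence[Polygon],
                       grid_pitch: float = float("nan")) -> RegionMask:
    """Build a RegionMask directly from known nest polygons (e.g. synthetic
    ground truth or an external annotation)."""
    polys = list(polygons)
    return RegionMask(polys, _label_cells(table, polys), float("nan"),
                      grid_pitch)


def signed_boundary_distance(table: CellTable, mask: RegionMask
                             ) -> BoundaryDistanceTable:
    """Euclidean distance to the nearest nest boundary, negated inside.

    An empty mask yields an invalid table (NaN distances), signalled via
    ``valid=False`` rather than infinities.
    """
    cell_ids = table.df["cell_id"].to_numpy()
    if mask.is_empty:
        df = pd.DataFrame({"cell_id": cell_ids,
                           "distance_um": np.full(len(cell_ids), np.nan),
                           "nearest_nest": np.full(len(cell_ids), -1)})
        return BoundaryDistanceTable(df, valid=False)
    xy = table.xy
    pts = shapely.points(xy[:, 0], xy[:, 1])
    boundary = unary_union([p.exterior for p in mask.polygons])
    d = shapely.distance(pts, boundary)
    union = unary_union(mask.polygons)
    inside = shapely.intersects_xy(union, xy[:, 0], xy[:, 1])
    signed = np.where(inside, -d, d)
    tree = shapely.STRtree(mask.polygons)
    nearest = tree.nearest(pts) if len(pts) else np.empty(0, int)
    df = pd.DataFrame({"cell_id": cell_ids, "distance_um": signed,
                       "nearest_nest": np.asarray(nearest, int)})
    return BoundaryDistanceTable(df, valid=True)


def attach_regions(table: CellTable, mask: RegionMask,
                   dist: BoundaryDistanceTable) -> CellTable:
    """Write region labels and signed distances back onto the cell table."""
    df = table.df.copy()
    df["region"] = mask.region.loc[df["cell_id"]].to_numpy()
    d = dist.df.set_index("cell_id")
    df["distance_um"] = d.loc[df["cell_id"], "distance_um"].to_numpy()
    df["nearest_nest"] = d.loc[df["cell_id"], "nearest_nest"].to_numpy()
    return CellTable(table.sample_id, df)


def distance_density_profile(df: pd.DataFrame,
                             group_by: Sequence[str],
                             bin_width: float = 25.0,
                             distance_col: str = "distance_um"
                             ) -> pd.DataFrame:
    """Normalised signed-distance histograms per group.

    ``df`` is a (possibly cohort-concatenated) cell table with the grouping
    labels and signed distances attached.  Bins are aligned so one edge
    falls exactly at 0 (the tumour boundary); each group's histogram is
    normalised to unit mass ("normalised cell count").  Empty groups are
    flagged by absence from the output.
    """
    for col in group_by:
        if col not in df.columns:
            raise ValueError(f"missing grouping column: {col!r}")
    d_all = df[distance_col].to_numpy(float)
    d_all = d_all[np.isfinite(d_all)]
    if len(d_all) == 0:
        return pd.DataFrame(columns=list(group_by) + ["bin_left", "bin_right",
                                                      "count", "density"])
    lo = np.floor(d_all.min() / bin_width) * bin_width
    hi = np.ceil(d_all.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    out = []
    for key, sub in df.groupby(list(group_by), observed=True, sort=True):
        d = sub[distance_col].to_numpy(float)
        d = d[np.isfinite(d)]
        if len(d) == 0:
            continue
        counts, _ = np.histogram(d, bins=edges)
        dens = counts / counts.sum()
        key = key if isinstance(key, tuple) else (key,)
        for b in range(len(edges) - 1):
            row = dict(zip(group_by, key))
            row.update({"bin_left": edges[b], "bin_right": edges[b + 1],
                        "count": int(counts[b]), "density": dens[b]})
            out.append(row)
    return pd.DataFrame(out)
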