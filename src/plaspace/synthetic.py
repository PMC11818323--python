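"""Synthetic tissue generator.

Forward model of the tissue geometry the analysis assumes: smooth-boundary
tumour nests in a stromal field, five cell types, proximity-ligation
(isPLA) positivity concentrated at the tumour boundary, and two response
archetypes -- a peritumoural macrophage *barrier* band (non-responder-like)
and B/T-cell aggregates near the boundary reminiscent of tertiary lymphoid
structures (*tls*, responder-like).  Every generated cohort comes with full
ground truth (true type, true isPLA state, compartment, nest polygons), so
each downstream stage can be tested as a parameter-recovery problem.

Cells are placed by inhomogeneous Poisson sampling per compartment; nests
are circles with a low-order Fourier radial perturbation, which keeps the
boundary smooth, simple and analytically tractable for distance oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union

from .core import CELL_TYPES, CHANNELS, CellTable, SampleMetadata

__all__ = [
    "TissueArchitecture", "GroundTruth", "generate_tissue", "generate_cohort",
    "recovery_architecture", "BARRIER", "TLS", "NEUTRAL",
]

BARRIER, TLS, NEUTRAL = "barrier", "tls", "neutral"

# Raw median-intensity means per cell type (arbitrary fluorescence units,
# typical of median per-cell export scales).  Off-target channels sit at a
# small bleed-through mean so phenotyping is not a trivial argmax.
_BLEED = 5.0
_DEFAULT_MARKER_MEANS: Dict[str, Dict[str, float]] = {
    "Tumour":     {"PanCK": 120.0},
    "B cell":     {"CD20": 100.0},
    "CD3 T cell": {"CD3e": 90.0},
    # cytotoxic T cells co-express CD3e, as in real tissue
    "CD8 T cell": {"CD3e": 70.0, "CD8": 90.0},
    "Macrophage": {"CD68": 110.0},
}


@dataclass
class TissueArchitecture:
    """Generator parameters for one synthetic tissue sample.

    Lengths in µm, areas in µm², densities in cells/µm².
    """

    archetype: str = NEUTRAL
    field_size: Tuple[float, float] = (1200.0, 1200.0)
    n_tumour_nests: int = 3
    nest_radius_mean: float = 180.0
    nest_radius_sd: float = 30.0
    nest_perturbation: float = 0.12      # relative Fourier amplitude
    tumour_density: float = 0.0040
    stroma_density: float = 0.0020
    tumour_mixture: Dict[str, float] = field(default_factory=lambda: {
        "Tumour": 0.96, "Macrophage": 0.02, "CD3 T cell": 0.02})
    # B cells are rare in diffuse stroma; they concentrate in the
    # follicle-like aggregates of the tls archetype
    stroma_mixture: Dict[str, float] = field(default_factory=lambda: {
        "B cell": 0.08, "CD3 T cell": 0.38, "CD8 T cell": 0.26,
        "Macrophage": 0.28})
    # barrier archetype: extra macrophage band hugging the tumour boundary
    barrier_band_width: float = 200.0
    barrier_macrophage_density: float = 0.0030
    # tls archetype: B/T aggregates centred 0-100 µm outside nest boundaries
    tls_aggregate_count: int = 3
    tls_aggregate_radius: float = 60.0
    tls_aggregate_density: float = 0.0100
    tls_mixture: Dict[str, float] = field(default_factory=lambda: {
        "B cell": 0.60, "CD3 T cell": 0.30, "CD8 T cell": 0.10})
    tls_offset_max: float = 100.0
    # isPLA forward model: P(positive) = p0 * exp(-|d|/scale), d = signed
    # distance to the nearest nest boundary
    ispla_boundary_scale: float = 100.0
    ispla_p0: float = 0.7
    # intensity models (log-normal)
    marker_means: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in
                                 _DEFAULT_MARKER_MEANS.items()})
    marker_log_sd: float = 0.40
    ispla_neg_median: float = 8.0
    ispla_pos_median: float = 80.0
    ispla_log_sd: float = 0.50
    dapi_median: float = 60.0
    dapi_log_sd: float = 0.30
    nuclear_area_log_mean: float = math.log(45.0)
    nuclear_area_log_sd: float = 0.35
    artifact_fraction: float = 0.03      # cells outside the 10-220 µm² window

    def __post_init__(self) -> None:
        if self.archetype not in (BARRIER, TLS, NEUTRAL):
            raise ValueError(f"unknown archetype: {self.archetype!r}")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field_size must have positive area")
        for name, mix in (("tumour_mixture", self.tumour_mixture),
                          ("stroma_mixture", self.stroma_mixture),
                          ("tls_mixture", self.tls_mixture)):
            if not mix:
                raise ValueError(f"{name} is empty")
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {s}, expected 1")
        if not 0.0 <= self.artifact_fraction < 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Per-cell ground truth and the generating nest polygons."""

    cells: pd.DataFrame          # cell_id, true_type, true_ispla, compartment,
                                 # true_distance_um
    nest_polygons: List[Polygon]
    archetype: str

    def nests_geojson(self) -> dict:
        feats = [{"type": "Feature",
                  "geometry": mapping(p),
                  "properties": {"nest_id": i, "area_um2": p.area}}
                 for i, p in enumerate(self.nest_polygons)]
        return {"type": "FeatureCollection", "features": feats}

    def save(self, directory, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / f"{stem}.truth.csv", index=False)
        with open(directory / f"{stem}.nests.geojson", "w") as fh:
            json.dump(self.nests_geojson(), fh)


# ---------------------------------------------------------------------------
# geometry helpers

def _nest_polygon(rng: np.random.Generator, centre: Tuple[float, float],
                  radius: float, amplitude: float, n_vertices: int = 256
                  ) -> Polygon:
    """Circle with low-order Fourier radial perturbation (orders 2-4)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, radius)
    for k in (2, 3, 4):
        a = rng.uniform(0.0, amplitude / k) * radius
        phi = rng.uniform(0.0, 2.0 * np.pi)
        r = r + a * np.cos(k * theta + phi)
    r = np.maximum(r, 0.2 * radius)
    xs = centre[0] + r * np.cos(theta)
    ys = centre[1] + r * np.sin(theta)
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:          # Fourier amplitudes are small; this is
        poly = poly.buffer(0)      # a belt-and-braces guard
    return poly


def _place_nests(rng: np.random.Generator, arch: TissueArchitecture
                 ) -> List[Polygon]:
    w, h = arch.field_size
    margin = min(arch.nest_radius_mean * 1.5, 0.45 * min(w, h))
    centres: List[Tuple[float, float]] = []
    min_sep = 2.3 * arch.nest_radius_mean
    for _ in range(500):
        if len(centres) == arch.n_tumour_nests:
            break
        c = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
        if all(math.hypot(c[0] - o[0], c[1] - o[1]) >= min_sep for o in centres):
            centres.append(c)
    # if the field is too crowded for full separation, relax gracefully
    while len(centres) < arch.n_tumour_nests:
        centres.append((rng.uniform(margin, w - margin),
                        rng.uniform(margin, h - margin)))
    polys = []
    for c in centres:
        radius = float(np.clip(rng.normal(arch.nest_radius_mean,
                                          arch.nest_radius_sd),
                               50.0, 0.45 * min(w, h)))
        polys.append(_nest_polygon(rng, c, radius, arch.nest_perturbation))
    return polys


def _sample_in_polygon(rng: np.random.Generator, poly: Polygon, n: int
                       ) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = []
    need = n
    while need > 0:
        m = max(int(need / max(poly.area / ((maxx - minx) * (maxy - miny)),
                               1e-3)) + 8, 32)
        pts = np.column_stack([rng.uniform(minx, maxx, m),
                               rng.uniform(miny, maxy, m)])
        keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        got = pts[keep][:need]
        out.append(got)
        need -= len(got)
    return np.concatenate(out)


def _signed_distance(xy: np.ndarray, nests: List[Polygon]) -> np.ndarray:
    """Negative inside a nest, positive outside; 0 on the boundary."""
    if len(xy) == 0:
        return np.empty(0)
    union = unary_union(nests)
    boundary = unary_union([p.exterior for p in nests])
    pts = shapely.points(xy[:, 0], xy[:, 1])
    d = shapely.distance(pts, boundary)
    inside = shapely.intersects_xy(union, xy[:, 0], xy[:, 1])
    return np.where(inside, -d, d)


# ---------------------------------------------------------------------------
# cell placement

def _draw_types(rng, mixture: Dict[str, float], n: int) -> np.ndarray:
    types = sorted(mixture)                     # deterministic order
    probs = np.array([mixture[t] for t in types])
    return np.asarray(types, dtype=object)[rng.choice(len(types), n, p=probs)]


def generate_tissue(arch: TissueArchitecture, seed: int,
                    sample_id: str = "sample") -> Tuple[CellTable, GroundTruth]:
    """Generate one synthetic tissue sample with ground truth.

    Reproducible: identical ``(arch, seed)`` gives an identical table.
    """
    rng = np.random.default_rng(seed)
    w, h = arch.field_size

    nests = _place_nests(rng, arch)
    union = unary_union(nests)

    xy_parts: List[np.ndarray] = []
    type_parts: List[np.ndarray] = []
    comp_parts: List[np.ndarray] = []

    # tumour compartment: per-nest Poisson
    for i, poly in enumerate(nests):
        n = rng.poisson(arch.tumour_density * poly.area)
        pts = _sample_in_polygon(rng, poly, n)
        xy_parts.append(pts)
        type_parts.append(_draw_types(rng, arch.tumour_mixture, n))
        comp_parts.append(np.full(n, f"nest_{i}", dtype=object))

    # stroma: uniform over the complement of the nest union
    stroma_area = w * h - union.area
    n_str = rng.poisson(arch.stroma_density * stroma_area)
    got = []
    need = n_str
    while need > 0:
        m = max(int(need * (w * h) / max(stroma_area, 1.0)) + 8, 32)
        pts = np.column_stack([rng.uniform(0, w, m), rng.uniform(0, h, m)])
        keep = ~shapely.intersects_xy(union, pts[:, 0], pts[:, 1])
        sel = pts[keep][:need]
        got.append(sel)
        need -= len(sel)
    pts = np.concatenate(got) if got else np.empty((0, 2))
    xy_parts.append(pts)
    type_parts.append(_draw_types(rng, arch.stroma_mixture, len(pts)))
    comp_parts.append(np.full(len(pts), "stroma", dtype=object))

    if arch.archetype == BARRIER:
        band = union.buffer(arch.barrier_band_width).difference(union)
        n_band = rng.poisson(arch.barrier_macrophage_density * band.area)
        pts = _sample_in_polygon(rng, band, n_band)
        # clip to field
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= w) &
                (pts[:, 1] >= 0) & (pts[:, 1] <= h))
        pts = pts[keep]
        xy_parts.append(pts)
        type_parts.append(np.full(len(pts), "Macrophage", dtype=object))
        comp_parts.append(np.full(len(pts), "barrier_band", dtype=object))

    aggregate_discs: List[Tuple[int, Polygon]] = []
    if arch.archetype == TLS and arch.tls_aggregate_count > 0:
        boundary = unary_union([p.exterior for p in nests])
        for j in range(arch.tls_aggregate_count):
            # centre: random boundary point pushed outward 0..offset_max
            s = rng.uniform(0.0, boundary.length)
            bp = boundary.interpolate(s)
            nearest = min(nests, key=lambda p: bp.distance(p.centroid))
            cx, cy = nearest.centroid.x, nearest.centroid.y
            vx, vy = bp.x - cx, bp.y - cy
            norm = math.hypot(vx, vy) or 1.0
            off = rng.uniform(0.0, arch.tls_offset_max)
            centre = Point(bp.x + vx / norm * off, bp.y + vy / norm * off)
            disc = centre.buffer(arch.tls_aggregate_radius).difference(union)
            if disc.is_empty:
                continue
            aggregate_discs.append((j, disc))
            n_agg = rng.poisson(arch.tls_aggregate_density * disc.area)
            pts = _sample_in_polygon(rng, disc, n_agg)
            keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= w) &
                    (pts[:, 1] >= 0) & (pts[:, 1] <= h))
            pts = pts[keep]
            xy_parts.append(pts)
            type_parts.append(_draw_types(rng, arch.tls_mixture, len(pts)))
            comp_parts.append(np.full(len(pts), f"aggregate_{j}", dtype=object))

    xy = np.concatenate(xy_parts) if xy_parts else np.empty((0, 2))
    types = np.concatenate(type_parts)
    comps = np.concatenate(comp_parts)
    n_cells = len(xy)

    # isPLA ground truth: positivity decays with distance from the boundary
    d = _signed_distance(xy, nests)

    # compartments are spatial regions: background-stroma cells that fall
    # inside the barrier band or an aggregate disc belong to that compartment
    if arch.archetype == BARRIER and n_cells:
        in_band = (comps == "stroma") & (d > 0) & (d <= arch.barrier_band_width)
        comps[in_band] = "barrier_band"
    if arch.archetype == TLS and aggregate_discs and n_cells:
        stroma_i = np.flatnonzero(comps == "stroma")
        for j, disc in aggregate_discs:
            if len(stroma_i) == 0:
                break
            hit = shapely.intersects_xy(disc, xy[stroma_i, 0], xy[stroma_i, 1])
            comps[stroma_i[hit]] = f"aggregate_{j}"
            stroma_i = stroma_i[~hit]
    p_pos = arch.ispla_p0 * np.exp(-np.abs(d) / arch.ispla_boundary_scale)
    true_pos = rng.uniform(size=n_cells) < p_pos

    # intensities
    inten = {c: np.empty(n_cells) for c in CHANNELS}
    log_noise = lambda n, sd: rng.normal(0.0, sd, n)
    for marker in ("PanCK", "CD20", "CD3e", "CD8", "CD68"):
        mean = np.full(n_cells, _BLEED)
        for t, mm in arch.marker_means.items():
            if marker in mm:
                mean[types == t] = mm[marker]
        inten[marker] = mean * np.exp(log_noise(n_cells, arch.marker_log_sd))
    base = np.where(true_pos, arch.ispla_pos_median, arch.ispla_neg_median)
    inten["isPLA"] = base * np.exp(log_noise(n_cells, arch.ispla_log_sd))
    inten["DAPI"] = arch.dapi_median * np.exp(log_noise(n_cells,
                                                        arch.dapi_log_sd))

    # nuclear area: in-window log-normal, resampled into [min, max]
    area = rng.lognormal(arch.nuclear_area_log_mean,
                         arch.nuclear_area_log_sd, n_cells)
    area = np.clip(area, 10.5, 219.0)

    # segmentation artefacts: out-of-window nuclei with dim DAPI
    n_art = rng.binomial(n_cells, arch.artifact_fraction) if n_cells else 0
    if n_art:
        idx = rng.choice(n_cells, n_art, replace=False)
        small = rng.uniform(size=n_art) < 0.5
        area[idx] = np.where(small,
                             rng.uniform(2.0, 9.0, n_art),
                             rng.uniform(230.0, 400.0, n_art))
        inten["DAPI"][idx] = 2.0 * np.exp(log_noise(n_art, arch.dapi_log_sd))
    is_artifact = np.zeros(n_cells, dtype=bool)
    if n_art:
        is_artifact[idx] = True

    cell_ids = np.array([f"{sample_id}-c{i:06d}" for i in range(n_cells)])
    df = pd.DataFrame({"cell_id": cell_ids, "x": xy[:, 0], "y": xy[:, 1],
                       "nuclear_area": area})
    for c in CHANNELS:
        df[c] = inten[c]
    table = CellTable(sample_id, df)

    truth = GroundTruth(
        cells=pd.DataFrame({
            "cell_id": cell_ids,
            "true_type": types,
            "true_ispla": true_pos,
            "compartment": comps,
            "true_distance_um": d,
            "is_artifact": is_artifact,
        }),
        nest_polygons=nests,
        archetype=arch.archetype,
    )
    return table, truth


def recovery_architecture() -> TissueArchitecture:
    """Identifiability-oriented architecture for parameter-recovery benchmarks.

    Compared with the realistic cohort defaults, compartments are made
    compositionally crisp -- near-pure mixtures, one large nest, a dense
    macrophage band and tight B-cell aggregates -- so that the planted
    compartment structure is recoverable in principle and any failure to
    recover it indicts the method, not the ground truth.  Use the plain
    defaults for the response-contrast analyses; use this for benchmarking
    neighbourhood discovery.
    """
    return TissueArchitecture(
        n_tumour_nests=1, nest_radius_mean=300.0, nest_radius_sd=20.0,
        tumour_mixture={"Tumour": 0.98, "Macrophage": 0.01,
                        "CD3 T cell": 0.01},
        stroma_mixture={"B cell": 0.05, "CD3 T cell": 0.75,
                        "CD8 T cell": 0.10, "Macrophage": 0.10},
        barrier_macrophage_density=0.010,
        tls_aggregate_density=0.030, tls_aggregate_radius=80.0,
        tls_mixture={"B cell": 0.85, "CD3 T cell": 0.10, "CD8 T cell": 0.05},
    )


# ---------------------------------------------------------------------------
# cohorts

#: Default per-group sample counts, matching the published study cohort.
DEFAULT_COHORT = {"CR": 2, "PR": 4, "SD": 2, "PD": 6}

#: Archetype used for each response group: progressive/stable disease gets
#: the macrophage-barrier geometry, responders get TLS-like aggregates.
GROUP_ARCHETYPE = {"CR": TLS, "PR": TLS, "SD": BARRIER, "PD": BARRIER}


def _jittered(arch: TissueArchitecture, rng: np.random.Generator
              ) -> TissueArchitecture:
    """Within-group biological spread: mild jitter of key scales."""
    import dataclasses
    return dataclasses.replace(
        arch,
        nest_radius_mean=arch.nest_radius_mean * rng.uniform(0.9, 1.1),
        ispla_boundary_scale=arch.ispla_boundary_scale * rng.uniform(0.9, 1.1),
        stroma_density=arch.stroma_density * rng.uniform(0.9, 1.1),
    )


def generate_cohort(n_per_group: Optional[Dict[str, int]] = None,
                    seed: int = 0,
                    base_arch: Optional[TissueArchitecture] = None
                    ) -> Tuple[List[CellTable], SampleMetadata,
                               List[GroundTruth]]:
    """Generate a cohort of synthetic samples with clinical metadata.

    PD/SD samples use the barrier archetype, CR/PR the tls archetype.
    Sub-seeds are drawn from ``seed`` so cohorts are reproducible.
    """
    if n_per_group is None:
        n_per_group = dict(DEFAULT_COHORT)
    for g, n in n_per_group.items():
        if g not in GROUP_ARCHETYPE:
            raise ValueError(f"unknown response group: {g!r}")
        if n < 0:
            raise ValueError("sample counts must be >= 0")
    rng = np.random.default_rng(seed)
    tables: List[CellTable] = []
    truths: List[GroundTruth] = []
    rows = []
    i = 0
    for group in ("CR", "PR", "SD", "PD"):
        for _ in range(n_per_group.get(group, 0)):
            import dataclasses
            arch = base_arch or TissueArchitecture()
            arch = dataclasses.replace(arch,
                                       archetype=GROUP_ARCHETYPE[group])
            arch = _jittered(arch, rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sid = f"S{i:02d}_{group}"
            t, gt = generate_tissue(arch, sub_seed, sample_id=sid)
            tables.append(t)
            truths.append(gt)
            rows.append({"sample_id": sid, "patient_id": f"P{i:02d}",
                         "response_group": group})
            i += 1
    meta = SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "response_group"]))
    return tables, meta, truths
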