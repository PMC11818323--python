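"""Pipeline configuration.

One flat dataclass carries every numeric parameter of the analysis so a run
is reproducible from a single artefact.  Defaults follow the published
protocol where one exists (QC nuclear-area window, arcsinh cofactor,
clustering k and resolution, nest-area floor, window sizes, thresholds);
parameters the protocol leaves open (DAPI floor, isPLA threshold, mask
contouring) carry implementation-chosen defaults documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class PipelineConfig:
    # --- QC (nuclear segmentation artefacts) ---
    qc_min_area: float = 10.0          # µm², inclusive
    qc_max_area: float = 220.0         # µm², inclusive
    qc_min_dapi: float = 5.0           # median DAPI floor; no published value

    # --- expression preprocessing ---
    arcsinh_cofactor: float = 150.0
    scaling: str = "zscore"            # "zscore" | "minmax" (pass-1 strategy)
    transform_area: bool = True        # arcsinh nuclear area with the markers

    # --- phenotyping (k-NN graph + Leiden) ---
    phenotype_knn_k: int = 30
    phenotype_resolution: float = 2.0

    # --- tumour mask ---
    mask_min_nest_area: float = 100.0  # µm²; nests at or below are dropped
    mask_grid_pitch: float = 20.0      # µm, density-raster pitch
    mask_sigma: float = 1.0            # Gaussian smoothing, grid-cell units
    mask_threshold: Optional[float] = None  # cells/µm²; None = auto

    # --- isPLA calling ---
    ispla_threshold: Optional[float] = None  # None = Otsu auto-estimate

    # --- proximity score ---
    proximity_radius: float = 20.0     # µm

    # --- cellular neighbourhoods ---
    cn_window_k: int = 10              # neighbours per window (Methods value;
                                       # the Results text mentions 6 — configurable)
    cn_k_range: Tuple[int, int] = (3, 15)
    cn_restarts: int = 10
    include_index_cell: bool = True    # window = cell + its k neighbours

    # --- spatial contexts ---
    sc_window_k: int = 100
    sc_threshold: float = 0.90         # minimal-combination cumulative rule
    scm_min_fraction: float = 1e-5     # 0.001% of cells, SCM node floor
    barycentric_purity: float = 0.9995

    # --- boundary-distance profiles ---
    bin_width: float = 25.0            # µm

    # --- barrier coverage summary ---
    coverage_distance: float = 30.0    # µm (d)
    coverage_min_cells: int = 3        # (m) isPLA+ macrophages within d
    boundary_step: float = 10.0        # µm arc-length sampling step

    # --- statistics ---
    p_correction: str = "benjamini-hochberg"  # or "none"
    exclude_sd: bool = True            # drop SD from headline contrasts

    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.qc_min_area < self.qc_max_area:
            raise ConfigError("qc_min_area must be < qc_max_area")
        if self.arcsinh_cofactor <= 0:
            raise ConfigError("arcsinh_cofactor must be positive")
        for name in ("phenotype_knn_k", "cn_window_k", "sc_window_k",
                     "cn_restarts", "coverage_min_cells"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("sc_threshold", "scm_min_fraction", "barycentric_purity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")
        lo, hi = self.cn_k_range
        if lo < 1 or hi < lo:
            raise ConfigError("cn_k_range must be a non-empty range of K >= 1")
        if self.proximity_radius <= 0:
            raise ConfigError("proximity_radius must be positive")
        if self.scaling not in ("zscore", "minmax"):
            raise ConfigError("scaling must be 'zscore' or 'minmax'")
        if self.p_correction not in ("benjamini-hochberg", "none"):
            raise ConfigError("p_correction must be 'benjamini-hochberg' or 'none'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cn_k_range" in d:
            d["cn_k_range"] = tuple(d["cn_k_range"])
        return cls(**d)
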