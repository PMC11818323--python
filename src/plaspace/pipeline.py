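"""End-to-end orchestration.

``run_pipeline`` sequences every stage -- QC/phenotyping, tumour mask and
signed distances, isPLA calling, proximity scores, CN discovery (both
variants), spatial contexts / SC maps / barycentric projection, and the
group statistics -- over a cohort of cell tables (real or synthetic),
writing labelled tables, models, graphs, stats and plots plus a run
manifest with content hashes, so identical configs rerun byte-identically
for the deterministic data artefacts (plots are excluded from the hash
manifest).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import (CELL_TYPES, CellTable, SampleMetadata, write_cell_table,
                   write_sample_metadata)
from .ispla import attach_ispla, classify_ispla, estimate_threshold, \
    positivity_fraction
from .neighborhoods import assign_cn, fit_neighbourhoods
from .phenotype import phenotype_cells
from .proximity import proximity_table
from .regions import (attach_regions, build_tumour_mask,
                      distance_density_profile, signed_boundary_distance)
from .spatial_context import (assign_spatial_context, barycentric_projection,
                              scm_graphs_by_group)
from .stats import (barrier_coverage, cell_frequencies,
                    kruskal_wallis_by_group, positivity_feature_table)
from .synthetic import generate_cohort

log = logging.getLogger("plaspace")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    tables: List[CellTable]
    metadata: SampleMetadata
    manifest: dict


def _default_triple(model) -> Optional[Tuple[int, int, int]]:
    """Pick the CN triple analogous to the published interface analysis:
    the tumour-dominated CN plus the two most tumour+immune-mixed CNs."""
    if model.K < 3:
        return None
    tumour_mass = np.array(
        [sum(c[j] for j, lab in enumerate(model.alphabet)
             if lab.startswith("Tumour")) for c in model.centroids])
    order = np.argsort(-tumour_mass)
    return tuple(int(i) for i in order[:3])


def run_pipeline(cfg: PipelineConfig, outdir,
                 tables: Optional[Sequence[CellTable]] = None,
                 metadata: Optional[SampleMetadata] = None,
                 n_per_group: Optional[Dict[str, int]] = None,
                 make_plots: bool = True) -> PipelineResult:
    """Run every stage over a cohort and write the output tree.

    Provide ``tables`` + ``metadata`` for existing data, or ``n_per_group``
    to simulate a synthetic cohort with ``cfg.random_seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: List[dict] = []

    def stage(name, **info):
        info = {"stage": name, "elapsed_s": round(time.time() - t0, 2), **info}
        stage_log.append(info)
        log.info("%s", info)

    if tables is None:
        if n_per_group is None:
            raise ValueError("provide input tables or a synthetic cohort spec")
        tables, metadata, truths = generate_cohort(n_per_group,
                                                   seed=cfg.random_seed)
        (outdir / "truth").mkdir(exist_ok=True)
        for t, gt in zip(tables, truths):
            gt.save(outdir / "truth", t.sample_id)
        stage("simulate", n_samples=len(tables),
              n_cells=sum(len(t) for t in tables))
    if metadata is None:
        raise ValueError("sample metadata required")
    groups = dict(zip(metadata.df["sample_id"], metadata.df["response_group"]))

    # --- QC + phenotyping (pooled cohort clustering) ---
    tables, pheno, qc_reports = phenotype_cells(tables, cfg)
    stage("phenotype", n_clusters=int(pheno.annotation["cluster"].max()) + 1,
          n_cells=sum(len(t) for t in tables))

    # --- tumour mask + signed distances ---
    masks = {}
    labelled = []
    for t in tables:
        mask = build_tumour_mask(t, cfg)
        dist = signed_boundary_distance(t, mask)
        labelled.append(attach_regions(t, mask, dist))
        masks[t.sample_id] = mask
    tables = labelled
    stage("mask_distance", n_nests={t.sample_id: len(masks[t.sample_id].polygons)
                                    for t in tables})

    # --- isPLA calling: one cohort-wide threshold ---
    thr = (cfg.ispla_threshold if cfg.ispla_threshold is not None
           else estimate_threshold(tables))
    tables = [attach_ispla(t, classify_ispla(t, threshold=thr))
              for t in tables]
    stage("ispla", threshold=thr)

    # --- proximity scores over all unordered type pairs ---
    pairs = list(itertools.combinations_with_replacement(CELL_TYPES, 2))
    prox = proximity_table(tables, pairs, radius=cfg.proximity_radius)
    stage("proximity", n_pairs=len(pairs))

    # --- cellular neighbourhoods, both variants ---
    cn_models = {}
    for variant in ("plain", "ispla_augmented"):
        model = fit_neighbourhoods(tables, cfg, variant=variant)
        tables = [assign_cn(model, t) for t in tables]
        cn_models[variant] = model
        stage("cn", variant=variant, selected_K=model.selected_K)

    # --- spatial contexts on the isPLA-augmented CNs ---
    sc_tables, freqs = [], {}
    n_cn = cn_models["ispla_augmented"].K
    for t in tables:
        t2, f = assign_spatial_context(t, cfg, cn_col="cn_label_pla",
                                       n_cn=n_cn)
        sc_tables.append(t2)
        freqs[t2.sample_id] = f
    tables = sc_tables
    scm = scm_graphs_by_group(tables, groups,
                              min_fraction=cfg.scm_min_fraction)
    stage("spatial_context",
          n_combinations={g: gph.number_of_nodes() for g, gph in scm.items()})

    triple = _default_triple(cn_models["ispla_augmented"])
    projections = {}
    if triple is not None:
        for t in tables:
            projections[t.sample_id] = barycentric_projection(
                freqs[t.sample_id], t, triple, purity=cfg.barycentric_purity)
        stage("barycentric", triple=list(triple))

    # --- summaries + statistics ---
    freq_tissue = cell_frequencies(tables, scope="tissue")
    freq_region = cell_frequencies(tables, scope="region")
    fractions = positivity_fraction(tables, by=("region", "cell_type"))
    feats = positivity_feature_table(fractions, metadata)
    if cfg.exclude_sd:
        feats_main = feats[feats["response_group"] != "SD"]
    else:
        feats_main = feats
    kw = (kruskal_wallis_by_group(feats_main, correction=cfg.p_correction)
          if feats_main["response_group"].nunique() >= 2 else pd.DataFrame())
    coverage = pd.DataFrame(
        [{"sample_id": t.sample_id,
          "response_group": groups[t.sample_id],
          "barrier_coverage": barrier_coverage(
              t, masks[t.sample_id], d=cfg.coverage_distance,
              m=cfg.coverage_min_cells, step=cfg.boundary_step)}
         for t in tables])
    merged = pd.concat([t.df.assign(sample_id=t.sample_id) for t in tables],
                       ignore_index=True)
    merged["response_group"] = merged["sample_id"].map(groups)
    profiles = distance_density_profile(
        merged.dropna(subset=["distance_um"]),
        group_by=("response_group", "cell_type", "ispla_positive"),
        bin_width=cfg.bin_width)
    stage("stats", n_features=len(kw))

    # --- write output tree ---
    data_files: List[Path] = []

    def write_df(df: pd.DataFrame, rel: str) -> None:
        p = outdir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, index=False)
        data_files.append(p)

    for t in tables:
        p = outdir / "cells" / f"{t.sample_id}.csv"
        write_cell_table(t, p)
        data_files.append(p)
    p = outdir / "metadata.csv"
    write_sample_metadata(metadata, p)
    data_files.append(p)
    for sid, mask in masks.items():
        p = outdir / "masks" / f"{sid}.geojson"
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "w") as fh:
            json.dump(mask.to_geojson(), fh)
        data_files.append(p)
    for variant, model in cn_models.items():
        p = outdir / "models" / f"cn_{variant}.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(model.to_json())
        data_files.append(p)
        write_df(pd.DataFrame({"K": sorted(model.inertia_curve),
                               "inertia": [model.inertia_curve[k] for k in
                                           sorted(model.inertia_curve)]}),
                 f"models/cn_{variant}_inertia.csv")
    import networkx as nx
    for g, gph in scm.items():
        p = outdir / "scm" / f"scm_{g}.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "w") as fh:
            json.dump(nx.node_link_data(gph, edges="edges"), fh, sort_keys=True)
        data_files.append(p)
    write_df(prox, "stats/proximity.csv")
    write_df(freq_tissue, "stats/cell_frequencies_tissue.csv")
    write_df(freq_region, "stats/cell_frequencies_region.csv")
    write_df(fractions, "stats/ispla_positivity.csv")
    if len(kw):
        kw_out = kw.copy()
        kw_out["group_medians"] = kw_out["group_medians"].map(json.dumps)
        write_df(kw_out, "stats/kruskal_wallis.csv")
    write_df(coverage, "stats/barrier_coverage.csv")
    write_df(profiles, "stats/distance_profiles.csv")
    for sid, proj in projections.items():
        write_df(proj.df, f"barycentric/{sid}.csv")

    if make_plots:
        from . import plots as P
        if len(profiles):
            mac = profiles[profiles["cell_type"] == "Macrophage"]
            if len(mac):
                P.distance_profile_panels(mac, outdir / "plots" /
                                          "distance_macrophage")
        for variant, model in cn_models.items():
            P.cn_composition_heatmap(model, outdir / "plots" /
                                     f"cn_heatmap_{variant}")
            P.inertia_curve_plot(model, outdir / "plots" /
                                 f"cn_inertia_{variant}")
        for g, gph in scm.items():
            P.scm_graph_plot(gph, outdir / "plots" / f"scm_{g}",
                             title=f"SC map, {g}")
        for sid, proj in projections.items():
            P.barycentric_plot(proj, outdir / "plots" / f"barycentric_{sid}",
                               title=sid)
        stage("plots")

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.random_seed,
        "qc_reports": [vars(r) for r in qc_reports],
        "stages": stage_log,
        "hashes": {str(p.relative_to(outdir)): _sha256(p)
                   for p in sorted(data_files)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return PipelineResult(outdir=outdir, tables=list(tables),
                          metadata=metadata, manifest=manifest)
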