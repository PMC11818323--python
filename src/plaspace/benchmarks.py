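"""Parameter-recovery and archetype-contrast benchmarks.

Self-contained experiments that generate ground-truthed synthetic cohorts,
run the pipeline stages, and measure how well each stage recovers the
planted structure: phenotype agreement, isPLA threshold accuracy,
neighbourhood-count selection, CN/compartment agreement, and the
responder/non-responder spatial contrasts (boundary-concentrated isPLA
signal, macrophage-tumour neighbourhood, barrier coverage, SC-map
interface prevalence).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, balanced_accuracy_score

from .config import PipelineConfig
from .core import CellTable
from .ispla import attach_ispla, classify_ispla, estimate_threshold
from .neighborhoods import assign_cn, fit_neighbourhoods
from .phenotype import phenotype_cells
from .regions import attach_regions, build_tumour_mask, \
    signed_boundary_distance
from .spatial_context import (assign_spatial_context,
                              tumour_macrophage_interface_fraction)
from .stats import barrier_coverage
from .synthetic import (TissueArchitecture, generate_cohort, generate_tissue,
                        recovery_architecture)

__all__ = ["parameter_recovery", "archetype_contrast", "attach_true_types"]


def attach_true_types(tables, truths) -> List[CellTable]:
    """Copy ground-truth cell types onto the tables as cell_type labels."""
    out = []
    for t, gt in zip(tables, truths):
        df = t.df.merge(gt.cells[["cell_id", "true_type"]], on="cell_id")
        out.append(CellTable(t.sample_id,
                             df.rename(columns={"true_type": "cell_type"})))
    return out


def compartment_classes(truth_cells: pd.DataFrame) -> pd.Series:
    """Collapse per-instance compartments (nest_0, aggregate_1, ...) to
    their structural class."""
    return truth_cells["compartment"].str.replace(r"_\d+$", "", regex=True)


def parameter_recovery(seed: int) -> Dict[str, float]:
    """Recovery benchmark on an identifiability-oriented two-sample cohort
    (one barrier-like, one tls-like sample; 4 planted compartment classes).

    Returns phenotyping agreement/ARI, the isPLA auto-threshold balanced
    accuracy, the Kneedle-selected neighbourhood count and the
    CN/compartment ARI (CN discovery run on ground-truth cell types so its
    score is not confounded by phenotyping errors).
    """
    cfg = PipelineConfig(random_seed=seed)
    tables, _, truths = generate_cohort({"CR": 1, "PD": 1}, seed=seed,
                                        base_arch=recovery_architecture())
    # --- phenotyping recovery (full QC/transform/cluster/annotate chain) ---
    labelled, _, _ = phenotype_cells(tables, cfg)
    type_aris, agreements = [], []
    for t, gt in zip(labelled, truths):
        m = t.df.merge(gt.cells, on="cell_id")
        type_aris.append(adjusted_rand_score(m["true_type"], m["cell_type"]))
        agreements.append(float((m["cell_type"] == m["true_type"]).mean()))

    # --- isPLA auto-threshold recovery ---
    thr = estimate_threshold(tables)
    baccs = []
    for t, gt in zip(tables, truths):
        call = classify_ispla(t, threshold=thr)
        m = gt.cells.set_index("cell_id").join(
            call.positive.rename("called"))
        baccs.append(balanced_accuracy_score(m["true_ispla"], m["called"]))

    # --- CN discovery on ground-truth types ---
    typed = attach_true_types(tables, truths)
    model = fit_neighbourhoods(typed, cfg, variant="plain")
    assigned = [assign_cn(model, t) for t in typed]
    cells = pd.concat([t.df.assign(sample_id=t.sample_id) for t in assigned])
    truth = pd.concat([gt.cells.assign(sample_id=t.sample_id)
                       for gt, t in zip(truths, assigned)])
    m = cells.merge(truth, on=["sample_id", "cell_id"])
    cn_ari = adjusted_rand_score(compartment_classes(m), m["cn_label"])

    return {
        "phenotype_ari": float(np.mean(type_aris)),
        "phenotype_agreement": float(np.mean(agreements)),
        "ispla_balanced_accuracy": float(np.mean(baccs)),
        "cn_selected_k": int(model.selected_K),
        "planted_compartments": 4,
        "cn_compartment_ari": float(cn_ari),
        "n_cells": int(sum(len(t) for t in tables)),
    }


def archetype_contrast(seed: int,
                       arch: TissueArchitecture | None = None
                       ) -> Dict[str, float]:
    """Headline spatial contrast on one matched barrier/tls sample pair
    (realistic cohort defaults, ground-truth cell types).

    Measures, for the barrier (non-responder-like) sample, the fraction of
    isPLA+ macrophage mass within 200 µm of the tumour boundary and the
    strongest macrophage+tumour CN centroid; and for both samples the
    barrier coverage and the SC-map tumour-macrophage interface fraction.
    """
    base = arch or TissueArchitecture()
    cfg = PipelineConfig(random_seed=seed)
    rng = np.random.default_rng(seed)
    s1, s2 = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
    tb, gtb = generate_tissue(dataclasses.replace(base, archetype="barrier"),
                              s1, sample_id="barrier")
    tt, gtt = generate_tissue(dataclasses.replace(base, archetype="tls"),
                              s2, sample_id="tls")
    tabs = attach_true_types([tb, tt], [gtb, gtt])
    thr = estimate_threshold(tabs)
    tabs = [attach_ispla(t, classify_ispla(t, threshold=thr)) for t in tabs]
    masks = {t.sample_id: build_tumour_mask(t, cfg) for t in tabs}
    tabs = [attach_regions(t, masks[t.sample_id],
                           signed_boundary_distance(t, masks[t.sample_id]))
            for t in tabs]

    d = tabs[0].df
    sel = (d["cell_type"] == "Macrophage") & d["ispla_positive"]
    mass_200 = float((d.loc[sel, "distance_um"].abs() <= 200).mean())

    model = fit_neighbourhoods(tabs, cfg, variant="plain")
    i_mac = model.alphabet.index("Macrophage")
    i_tum = model.alphabet.index("Tumour")
    mac_tum = model.centroids[:, [i_mac, i_tum]].sum(axis=1)
    # the macrophage-led mixed neighbourhood, not the pure tumour CN
    mac_led = [j for j in range(model.K)
               if model.centroids[j, i_mac] >= model.centroids[j, i_tum]]
    max_mac_tum = float(mac_tum[mac_led].max()) if mac_led else 0.0

    out = {"ispla_macrophage_mass_within_200um": mass_200,
           "max_macrophage_tumour_centroid": max_mac_tum}
    for t in tabs:
        t = assign_cn(model, t)
        t2, _ = assign_spatial_context(t, cfg, cn_col="cn_label",
                                       n_cn=model.K)
        out[f"coverage_{t.sample_id}"] = barrier_coverage(
            t2, masks[t.sample_id], d=cfg.coverage_distance,
            m=cfg.coverage_min_cells, step=cfg.boundary_step)
        out[f"interface_fraction_{t.sample_id}"] = \
            tumour_macrophage_interface_fraction(
                list(t2.df["sc_combination"]), model)
    return out
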