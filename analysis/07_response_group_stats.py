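"""Response-group statistics.

Cell-type percentages per tissue and per tumour/stroma region,
Kruskal-Wallis tests of isPLA positivity fractions across response groups
(SD excluded from the headline contrast, Benjamini-Hochberg corrected over
the region x cell-type family), barrier coverage per sample, and the
SC-map tumour-macrophage interface fraction per group.
"""

import argparse
from pathlib import Path

import pandas as pd

import plaspace as pl
from plaspace.stats import positivity_feature_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    cfg = pl.PipelineConfig()
    meta = pl.read_sample_metadata(args.cohort / "metadata.csv")
    groups = dict(zip(meta.df["sample_id"], meta.df["response_group"]))
    tables = [pl.read_cell_table(p) for p in
              sorted((args.cohort / "cells").glob("*.csv"))]

    pl.cell_frequencies(tables, scope="tissue").to_csv(
        args.cohort / "cell_frequencies_tissue.csv", index=False)
    pl.cell_frequencies(tables, scope="region").to_csv(
        args.cohort / "cell_frequencies_region.csv", index=False)

    fractions = pl.positivity_fraction(tables, by=("region", "cell_type"))
    feats = positivity_feature_table(fractions, meta)
    if cfg.exclude_sd:
        feats = feats[feats["response_group"] != "SD"]
    kw = pl.kruskal_wallis_by_group(feats, correction=cfg.p_correction)
    kw_out = kw.copy()
    kw_out["group_medians"] = kw_out["group_medians"].astype(str)
    kw_out.to_csv(args.cohort / "kruskal_wallis.csv", index=False)
    n_sig = int((kw["p_adj"] < 0.05).sum())
    print(f"Kruskal-Wallis across response groups: {len(kw)} features, "
          f"{n_sig} significant after correction")
    print(kw.nsmallest(3, "p")[["feature", "H", "p", "p_adj"]]
          .to_string(index=False))

    import json
    cov_rows = []
    for t in tables:
        mask_geo = json.loads(
            (args.cohort / "masks" / f"{t.sample_id}.geojson").read_text())
        from shapely.geometry import shape
        polys = [shape(f["geometry"]) for f in mask_geo["features"]]
        mask = pl.mask_from_polygons(t, polys)
        cov_rows.append({
            "sample_id": t.sample_id,
            "response_group": groups[t.sample_id],
            "barrier_coverage": pl.barrier_coverage(
                t, mask, d=cfg.coverage_distance, m=cfg.coverage_min_cells,
                step=cfg.boundary_step)})
    cov = pd.DataFrame(cov_rows)
    cov.to_csv(args.cohort / "barrier_coverage.csv", index=False)
    print("mean barrier coverage by group:")
    print(cov.groupby("response_group")["barrier_coverage"].mean().round(3)
          .to_string())

    model = pl.NeighbourhoodModel.from_json(
        (args.cohort / "models" / "cn_ispla_augmented.json").read_text())
    rows = []
    for g in sorted(set(groups.values())):
        combos = []
        for t in tables:
            if groups[t.sample_id] == g:
                combos.extend(t.df["sc_combination"])
        rows.append({"response_group": g,
                     "interface_fraction":
                         pl.tumour_macrophage_interface_fraction(combos,
                                                                 model)})
    ifc = pd.DataFrame(rows)
    ifc.to_csv(args.cohort / "interface_fraction.csv", index=False)
    print("tumour-macrophage SC interface fraction by group:")
    print(ifc.to_string(index=False))


if __name__ == "__main__":
    main()
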