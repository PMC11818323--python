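"""Cellular-neighbourhood discovery.

Fits both CN variants on window compositions pooled across the cohort
(windows of each cell's 10 nearest neighbours): the plain cell-type
alphabet and the isPLA-augmented alphabet (cell type x PLA+/-).  K is
selected by the Kneedle elbow of the KMeans inertia curve over K=3..15.
Writes the fitted models, inertia curves, heatmaps and per-cell labels.
"""

import argparse
from pathlib import Path

import pandas as pd

import plaspace as pl
from plaspace import plots

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = pl.PipelineConfig(random_seed=args.seed)
    tables = [pl.read_cell_table(p) for p in
              sorted((args.cohort / "cells").glob("*.csv"))]
    (args.cohort / "models").mkdir(exist_ok=True)

    for variant in ("plain", "ispla_augmented"):
        model = pl.fit_neighbourhoods(tables, cfg, variant=variant)
        tables = [pl.assign_cn(model, t) for t in tables]
        (args.cohort / "models" / f"cn_{variant}.json").write_text(
            model.to_json())
        pd.DataFrame({"K": sorted(model.inertia_curve),
                      "inertia": [model.inertia_curve[k]
                                  for k in sorted(model.inertia_curve)]}
                     ).to_csv(args.cohort / "models" /
                              f"cn_{variant}_inertia.csv", index=False)
        plots.cn_composition_heatmap(model,
                                     args.cohort / "plots" /
                                     f"cn_heatmap_{variant}")
        plots.inertia_curve_plot(model,
                                 args.cohort / "plots" /
                                 f"cn_inertia_{variant}")
        print(f"{variant}: selected K = {model.selected_K}")
        for j, name in enumerate(model.cn_names()):
            print(f"  CN{j}: {name}")

    for t in tables:
        pl.write_cell_table(t, args.cohort / "cells" / f"{t.sample_id}.csv")


if __name__ == "__main__":
    main()
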