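"""Spatial contexts, SC maps and barycentric interface projections.

Assigns every cell its minimal CN combination (the shortest abundance-
ordered set of isPLA-augmented CNs exceeding 90% of its 100-neighbour
window), builds one SC-map graph per response group (nodes = combinations
above 0.001% of cells, edges to one-larger supersets), and projects
near-pure windows (99.95% mass) of the most tumour-heavy CN triple onto a
barycentric triangle per sample.
"""

import argparse
import json
from pathlib import Path

import networkx as nx
import numpy as np

import plaspace as pl
from plaspace import plots
from plaspace.pipeline import _default_triple

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = pl.PipelineConfig(random_seed=args.seed)
    meta = pl.read_sample_metadata(args.cohort / "metadata.csv")
    groups = dict(zip(meta.df["sample_id"], meta.df["response_group"]))
    model = pl.NeighbourhoodModel.from_json(
        (args.cohort / "models" / "cn_ispla_augmented.json").read_text())

    tables, freqs = [], {}
    for p in sorted((args.cohort / "cells").glob("*.csv")):
        t = pl.read_cell_table(p)
        t, f = pl.assign_spatial_context(t, cfg, cn_col="cn_label_pla",
                                         n_cn=model.K)
        pl.write_cell_table(t, p)
        tables.append(t)
        freqs[t.sample_id] = f

    scm = pl.scm_graphs_by_group(tables, groups,
                                 min_fraction=cfg.scm_min_fraction)
    (args.cohort / "scm").mkdir(exist_ok=True)
    for g, gph in scm.items():
        with open(args.cohort / "scm" / f"scm_{g}.json", "w") as fh:
            json.dump(nx.node_link_data(gph, edges="edges"), fh,
                      sort_keys=True)
        plots.scm_graph_plot(gph, args.cohort / "plots" / f"scm_{g}",
                             title=f"SC map, {g}")
        top = sorted(gph.nodes(data=True), key=lambda kv: -kv[1]["fraction"])
        shown = ", ".join(f"{k} ({d['fraction']:.1%})" for k, d in top[:4])
        print(f"  {g}: {gph.number_of_nodes()} combinations; top: {shown}")

    triple = _default_triple(model)
    if triple is not None:
        (args.cohort / "barycentric").mkdir(exist_ok=True)
        for t in tables:
            proj = pl.barycentric_projection(freqs[t.sample_id], t, triple,
                                             purity=cfg.barycentric_purity)
            proj.df.to_csv(args.cohort / "barycentric" /
                           f"{t.sample_id}.csv", index=False)
            plots.barycentric_plot(proj, args.cohort / "plots" /
                                   f"barycentric_{t.sample_id}", title=t.sample_id)
        print(f"barycentric triple: CNs {triple} "
              f"({[model.cn_names()[i] for i in triple]})")


if __name__ == "__main__":
    main()
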