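"""Cohort summaries and response-group comparisons.

Cell-type frequencies (percentages per tissue or per tumour/stroma region),
Kruskal-Wallis tests of per-sample features across response groups with
Benjamini-Hochberg correction over the feature family, and a barrier
coverage metric that operationalises the peritumoural macrophage-barrier
phenotype: the fraction of the tumour-boundary arc length that has at
least ``m`` isPLA-positive macrophages within distance ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree
from shapely.ops import unary_union
from statsmodels.stats.multitest import multipletests

from .core import CellTable
from .regions import RegionMask

__all__ = ["cell_frequencies", "kruskal_wallis_by_group", "barrier_coverage"]


def cell_frequencies(tables, scope: str = "tissue") -> pd.DataFrame:
    """Cell-type percentages per sample (``scope='tissue'``) or per
    sample x tumour/stroma region (``scope='region'``).

    Percentages sum to 100 within each scope unit; empty regions are
    simply absent (missing entries, not zeros).
    """
    if isinstance(tables, CellTable):
        tables = [tables]
    if scope not in ("tissue", "region"):
        raise ValueError("scope must be 'tissue' or 'region'")
    rows = []
    for t in tables:
        df = t.df
        if "cell_type" not in df.columns:
            raise ValueError("cell_type labels required")
        keys = ["region", "cell_type"] if scope == "region" else ["cell_type"]
        if scope == "region" and "region" not in df.columns:
            raise ValueError("region labels required for scope='region'")
        counts = df.groupby(keys, observed=True).size().rename("n").reset_index()
        denom_keys = ["region"] if scope == "region" else []
        if denom_keys:
            counts["total"] = counts.groupby(denom_keys)["n"].transform("sum")
        else:
            counts["total"] = counts["n"].sum()
        counts["percentage"] = 100.0 * counts["n"] / counts["total"]
        counts.insert(0, "sample_id", t.sample_id)
        rows.append(counts.drop(columns="total"))
    return pd.concat(rows, ignore_index=True)


def kruskal_wallis_by_group(features: pd.DataFrame,
                            group_col: str = "response_group",
                            value_col: str = "value",
                            feature_col: str = "feature",
                            correction: str = "benjamini-hochberg"
                            ) -> pd.DataFrame:
    """Kruskal-Wallis H across response groups, per feature, with the
    adjustment applied over the whole feature family.

    ``features`` is tidy: one row per (sample, feature) observation with
    the sample's group.  Features seen in fewer than two groups raise;
    all-identical values yield H = 0, p = 1 (every rank tied).
    """
    if correction not in ("benjamini-hochberg", "none"):
        raise ValueError("correction must be 'benjamini-hochberg' or 'none'")
    rows = []
    for feat, sub in features.groupby(feature_col, sort=True):
        samples = [g[value_col].to_numpy(float)
                   for _, g in sub.groupby(group_col, observed=True)
                   if len(g) > 0]
        if len(samples) < 2:
            raise ValueError(f"feature {feat!r}: need >= 2 groups")
        pooled = np.concatenate(samples)
        medians = {g: float(np.median(v[value_col]))
                   for g, v in sub.groupby(group_col, observed=True)}
        if np.ptp(pooled) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        rows.append({"feature": feat, "H": float(h), "p": float(p),
                     "n": int(len(pooled)), "group_medians": medians})
    out = pd.DataFrame(rows)
    if len(out) and correction == "benjamini-hochberg":
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p"] if len(out) else []
    return out


def positivity_feature_table(fractions: pd.DataFrame,
                             metadata) -> pd.DataFrame:
    """Reshape the positivity-fraction table into the tidy feature format
    expected by :func:`kruskal_wallis_by_group` (feature = region x type)."""
    df = fractions.merge(metadata.df[["sample_id", "response_group"]],
                         on="sample_id")
    df = df.dropna(subset=["fraction"])
    df["feature"] = df["region"].astype(str) + "/" + df["cell_type"].astype(str)
    return df.rename(columns={"fraction": "value"})[
        ["sample_id", "response_group", "feature", "value"]]


def barrier_coverage(table: CellTable, mask: RegionMask, d: float = 30.0,
                     m: int = 1, step: float = 10.0) -> float:
    """Fraction of tumour-boundary length covered by isPLA+ macrophages.

    Nest boundaries are sampled at ``step`` µm arc-length intervals; a
    boundary point is covered when at least ``m`` isPLA-positive
    macrophages lie within ``d`` µm.  Returns NaN (flagged) for an empty
    boundary.
    """
    if mask.is_empty:
        return float("nan")
    for col in ("cell_type", "ispla_positive"):
        if col not in table.df.columns:
            raise ValueError(f"missing column: {col!r}")
    pts = []
    for poly in mask.polygons:
        ext = poly.exterior
        for s in np.arange(0.0, ext.length, step):
            p = ext.interpolate(s)
            pts.append((p.x, p.y))
    if not pts:
        return float("nan")
    pts = np.asarray(pts)
    sel = ((table.df["cell_type"] == "Macrophage") &
           table.df["ispla_positive"].astype(bool))
    mac = table.xy[sel.to_numpy()]
    if len(mac) == 0:
        return 0.0
    tree = cKDTree(mac)
    counts = tree.query_ball_point(pts, r=d, return_length=True)
    return float(np.mean(counts >= m))
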