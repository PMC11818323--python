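"""isPLA positivity calling and positivity fractions.

A proximity-ligation (isPLA) spot is produced only when PD-1 and PD-L1 sit
within ~40 nm of each other, so per-cell isPLA intensity reads out ongoing
receptor-ligand engagement rather than mere co-expression.  Cells are
called positive with a single global intensity threshold applied uniformly
to every sample (one consistent criterion across slides); ``threshold=None``
estimates that threshold cohort-wide by Otsu's method on pooled
log-intensities, which splits the bimodal positive/negative mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import CellTable


@dataclass
class IsplaCall:
    """Per-cell positivity for one sample, plus the threshold applied."""

    positive: pd.Series            # index cell_id, bool
    threshold: float


def estimate_threshold(tables: Sequence[CellTable]) -> float:
    """Cohort-wide Otsu threshold on pooled log1p isPLA intensities,
    mapped back to the intensity scale."""
    pooled = np.concatenate([t.df["isPLA"].to_numpy(float) for t in tables])
    if not np.isfinite(pooled).all():
        raise ValueError("non-finite isPLA intensities")
    if len(pooled) == 0 or np.ptp(pooled) == 0:
        raise ValueError("cannot estimate a threshold from constant input")
    t_log = threshold_otsu(np.log1p(pooled))
    return float(np.expm1(t_log))


def classify_ispla(table: CellTable,
                   threshold: Optional[float] = None,
                   cohort: Optional[Sequence[CellTable]] = None) -> IsplaCall:
    """Call isPLA positivity: positive iff intensity >= threshold.

    ``threshold=None`` auto-estimates one global threshold from ``cohort``
    (defaulting to the sample itself) so that all samples of a study share
    a single criterion.
    """
    x = table.df["isPLA"].to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite isPLA intensities")
    if threshold is None:
        threshold = estimate_threshold(cohort if cohort is not None else [table])
    pos = pd.Series(x >= threshold, index=table.df["cell_id"].to_numpy(),
                    name="ispla_positive")
    return IsplaCall(positive=pos, threshold=float(threshold))


def attach_ispla(table: CellTable, call: IsplaCall) -> CellTable:
    df = table.df.copy()
    df["ispla_positive"] = call.positive.loc[df["cell_id"]].to_numpy()
    return CellTable(table.sample_id, df)


def positivity_fraction(tables: Union[CellTable, Sequence[CellTable]],
                        by: Sequence[str] = ("region", "cell_type")
                        ) -> pd.DataFrame:
    """Fraction of isPLA-positive cells per sample and grouping.

    Output is tidy: sample_id, the grouping columns, n, n_positive,
    fraction.  Groups with zero cells are simply absent (missing, not 0).
    """
    if isinstance(tables, CellTable):
        tables = [tables]
    rows = []
    for t in tables:
        df = t.df
        for col in list(by) + ["ispla_positive"]:
            if col not in df.columns:
                raise ValueError(f"missing column: {col!r}")
        g = df.groupby(list(by), observed=True, sort=True)["ispla_positive"]
        agg = g.agg(n="size", n_positive="sum").reset_index()
        agg.insert(0, "sample_id", t.sample_id)
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", *by, "n", "n_positive"])
    out["n_positive"] = out["n_positive"].astype(int)
    out["fraction"] = out["n_positive"] / out["n"]
    return out
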