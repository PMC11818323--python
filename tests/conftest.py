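"""Shared fixtures: programmatically generated cell tables and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import plaspace as pl
from plaspace.core import CELL_TYPES, CHANNELS


def make_table(n: int, seed: int = 0, sample_id: str = "T",
               field: float = 1000.0, types=None) -> pl.CellTable:
    """Random but valid cell table: uniform positions, log-normal signal."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "cell_id": [f"{sample_id}-{i}" for i in range(n)],
        "x": rng.uniform(0, field, n),
        "y": rng.uniform(0, field, n),
        "nuclear_area": rng.uniform(15, 200, n),
    })
    for c in CHANNELS:
        df[c] = rng.lognormal(2.0, 0.5, n)
    if types is not None:
        df["cell_type"] = rng.choice(types, n)
    return pl.CellTable(sample_id, df)


@pytest.fixture(scope="session")
def default_cfg() -> pl.PipelineConfig:
    return pl.PipelineConfig(random_seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """One responder-like and one non-responder-like synthetic sample."""
    return pl.generate_cohort({"CR": 1, "PD": 1}, seed=0)


@pytest.fixture(scope="session")
def phenotyped_cohort(small_cohort, default_cfg):
    tables, meta, truths = small_cohort
    labelled, result, reports = pl.phenotype_cells(tables, default_cfg)
    return labelled, meta, truths, result, reports


@pytest.fixture(scope="session")
def typed_cohort(small_cohort):
    """Cohort with ground-truth cell types attached as cell_type labels
    (isolates spatial stages from phenotyping)."""
    tables, meta, truths = small_cohort
    out = []
    for t, gt in zip(tables, truths):
        df = t.df.merge(gt.cells[["cell_id", "true_type"]], on="cell_id")
        df = df.rename(columns={"true_type": "cell_type"})
        out.append(pl.CellTable(t.sample_id, df))
    return out, meta, truths
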