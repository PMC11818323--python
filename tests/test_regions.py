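"""Tumour mask construction and signed boundary distances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

import plaspace as pl
from plaspace.core import CHANNELS
from plaspace.regions import (build_tumour_mask, distance_density_profile,
                              mask_from_polygons, signed_boundary_distance)


def _table_from_xy(xy, types, sample_id="T"):
    n = len(xy)
    df = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                       "x": xy[:, 0], "y": xy[:, 1],
                       "nuclear_area": np.full(n, 50.0)})
    for c in CHANNELS:
        df[c] = 10.0
    df["cell_type"] = types
    return pl.CellTable(sample_id, df)


def _disc_tissue(seed, r=200.0, centre=(500.0, 500.0), field=1000.0):
    rng = np.random.default_rng(seed)
    n_t = rng.poisson(0.004 * np.pi * r * r)
    rr = r * np.sqrt(rng.uniform(size=n_t))
    th = rng.uniform(0, 2 * np.pi, n_t)
    tum = np.column_stack([centre[0] + rr * np.cos(th),
                           centre[1] + rr * np.sin(th)])
    n_s = rng.poisson(0.0005 * field * field)
    stro = rng.uniform(0, field, (n_s, 2))
    xy = np.vstack([tum, stro])
    types = np.array(["Tumour"] * n_t + ["CD3 T cell"] * n_s, dtype=object)
    return _table_from_xy(xy, types)


def test_dense_disc_recovers_area_within_15_percent(default_cfg):
    for seed in range(5):
        mask = build_tumour_mask(_disc_tissue(seed), default_cfg)
        assert len(mask.polygons) >= 1
        est = sum(mask.nest_areas)
        true = np.pi * 200.0 ** 2
        assert abs(est - true) / true < 0.15


def test_min_nest_area_rule_drops_tiny_cluster():
    """A handful of tumour cells spanning a few µm² never becomes a tumour
    annotation: the nest-area floor removes it."""
    rng = np.random.default_rng(0)
    tiny = np.array([[500.0, 500.0]]) + rng.uniform(-2, 2, (5, 2))
    stroma = rng.uniform(0, 1000, (300, 2))
    xy = np.vstack([tiny, stroma])
    types = np.array(["Tumour"] * 5 + ["B cell"] * 300, dtype=object)
    table = _table_from_xy(xy, types)
    fine = pl.PipelineConfig(mask_grid_pitch=2.0, mask_sigma=1.0)
    masked = build_tumour_mask(table, fine)
    assert masked.is_empty
    # with the floor disabled the same contour IS found: the rule is what
    # removes it
    no_floor = pl.PipelineConfig(mask_grid_pitch=2.0, mask_sigma=1.0,
                                 mask_min_nest_area=1e-6)
    assert len(build_tumour_mask(table, no_floor).polygons) >= 1


def test_no_tumour_cells_gives_empty_mask_all_stroma(default_cfg):
    rng = np.random.default_rng(1)
    table = _table_from_xy(rng.uniform(0, 500, (100, 2)),
                           np.array(["B cell"] * 100, dtype=object))
    with pytest.warns(UserWarning, match="no tumour cells"):
        mask = build_tumour_mask(table, default_cfg)
    assert mask.is_empty
    assert set(mask.region) == {"stroma"}
    dist = signed_boundary_distance(table, mask)
    assert not dist.valid
    assert dist.df["distance_um"].isna().all()


def test_square_nest_distances():
    square = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
    xy = np.array([[50.0, 50.0], [130.0, 50.0]])
    table = _table_from_xy(xy, np.array(["Tumour", "B cell"], dtype=object))
    mask = mask_from_polygons(table, [square])
    d = signed_boundary_distance(table, mask).df["distance_um"]
    assert d[0] == pytest.approx(-50.0)
    assert d[1] == pytest.approx(+30.0)
    assert list(mask.region) == ["tumour", "stroma"]


def test_circle_distance_matches_analytic_oracle():
    """|signed distance| to a finely discretised circular nest equals
    |r - R| from the analytic circle geometry."""
    R, C, n_v = 200.0, np.array([300.0, 300.0]), 50_000
    th = np.linspace(0, 2 * np.pi, n_v, endpoint=False)
    circle = Polygon(np.column_stack([C[0] + R * np.cos(th),
                                      C[1] + R * np.sin(th)]))
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 600, (1000, 2))
    table = _table_from_xy(xy, np.array(["B cell"] * 1000, dtype=object))
    mask = mask_from_polygons(table, [circle])
    d = signed_boundary_distance(table, mask).df["distance_um"].to_numpy()
    r = np.hypot(*(xy - C).T)
    np.testing.assert_allclose(np.abs(d), np.abs(r - R), atol=1e-6)
    # sign consistency with the point-in-polygon region label
    inside = r < R
    assert np.array_equal(d <= 0, inside)


def test_region_label_and_distance_sign_consistent(typed_cohort, default_cfg):
    tables, _, _ = typed_cohort
    t = tables[0]
    mask = build_tumour_mask(t, default_cfg)
    dist = signed_boundary_distance(t, mask)
    att = pl.attach_regions(t, mask, dist)
    tum = att.df["region"] == "tumour"
    assert ((att.df["distance_um"] <= 0) == tum).all()


def test_mask_translation_equivariance(default_cfg):
    t = _disc_tissue(7)
    m1 = build_tumour_mask(t, default_cfg)
    df = t.df.copy()
    df["x"] += 321.5
    df["y"] -= 123.25
    m2 = build_tumour_mask(pl.CellTable("T", df), default_cfg)
    assert len(m1.polygons) == len(m2.polygons)
    for p1, p2 in zip(m1.polygons, m2.polygons):
        assert p1.area == pytest.approx(p2.area, rel=1e-9)
        assert p2.centroid.x - p1.centroid.x == pytest.approx(321.5, abs=1e-6)
        assert p2.centroid.y - p1.centroid.y == pytest.approx(-123.25,
                                                              abs=1e-6)


def test_lower_threshold_never_shrinks_mask(default_cfg):
    t = _disc_tissue(11)
    base = build_tumour_mask(t, default_cfg)
    lower = dataclasses.replace(default_cfg,
                                mask_threshold=base.threshold * 0.5)
    grown = build_tumour_mask(t, lower)
    assert sum(grown.nest_areas) >= sum(base.nest_areas) - 1e-9


class TestDistanceProfile:
    def test_point_mass_in_single_bin(self):
        df = pd.DataFrame({"distance_um": [10.0] * 5, "g": ["a"] * 5})
        out = distance_density_profile(df, ["g"], bin_width=50.0)
        assert out.loc[out["density"] > 0, "bin_left"].tolist() == [0.0]
        assert out["density"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_profiles_normalised_per_group(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"distance_um": rng.normal(0, 100, 400),
                           "g": rng.choice(["a", "b"], 400)})
        out = distance_density_profile(df, ["g"], bin_width=25.0)
        sums = out.groupby("g")["density"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        # bins aligned to the boundary at 0
        assert (np.abs(out["bin_left"] / 25.0
                       - np.round(out["bin_left"] / 25.0)) < 1e-9).all()

    def test_empty_group_absent(self):
        df = pd.DataFrame({"distance_um": [np.nan, 5.0],
                           "g": ["empty", "ok"]})
        out = distance_density_profile(df, ["g"], bin_width=10.0)
        assert set(out["g"]) == {"ok"}
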