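"""QC, transforms, clustering and cluster annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import plaspace as pl
from plaspace.phenotype import (ExpressionMatrix, annotate_clusters,
                                arcsinh_transform, cluster_cells, dual_scale,
                                expression_matrix, qc_filter)

from conftest import make_table


def _with_areas(areas, dapi=100.0):
    t = make_table(len(areas), seed=0)
    df = t.df.copy()
    df["nuclear_area"] = areas
    df["DAPI"] = dapi
    return pl.CellTable("T", df)


class TestQC:
    def test_area_window_is_closed(self, default_cfg):
        out, rep = qc_filter(_with_areas([5.0, 50.0, 250.0]), default_cfg)
        assert list(out.df["nuclear_area"]) == [50.0]
        assert (rep.n_removed_small, rep.n_removed_large) == (1, 1)
        out, _ = qc_filter(_with_areas([10.0, 220.0]), default_cfg)
        assert len(out) == 2                      # boundary values retained

    def test_dapi_floor_empties_table_with_full_report(self, default_cfg):
        table = _with_areas([50.0, 60.0], dapi=0.1)
        with pytest.warns(UserWarning):
            out, rep = qc_filter(table, default_cfg)
        assert len(out) == 0
        assert rep.n_removed_dapi == 2
        assert (rep.n_removed_small + rep.n_removed_large +
                rep.n_removed_dapi + rep.n_retained) == rep.n_input

    def test_idempotent(self, default_cfg):
        t, _ = qc_filter(_with_areas([5.0, 50.0, 80.0, 250.0]), default_cfg)
        t2, rep2 = qc_filter(t, default_cfg)
        assert t2.df.equals(t.df)
        assert rep2.n_retained == rep2.n_input


class TestArcsinh:
    def test_closed_forms(self):
        m = ExpressionMatrix(pd.DataFrame({"PanCK": [0.0, 150.0]}), "raw")
        out = arcsinh_transform(m, cofactor=150.0)
        assert out.data["PanCK"][0] == 0.0
        assert out.data["PanCK"][1] == pytest.approx(math.log(1 + math.sqrt(2)),
                                                     abs=1e-12)
        assert out.stage == "arcsinh"

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1e4, (1000, 2))
        lo, hi = x.min(axis=1), x.max(axis=1)
        m = ExpressionMatrix(pd.DataFrame({"a": lo, "b": hi + 1e-9}), "raw")
        out = arcsinh_transform(m, 150.0).data
        assert (out["a"] < out["b"]).all()

    def test_invalid_cofactor(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0]}), "raw")
        with pytest.raises(ValueError):
            arcsinh_transform(m, 0.0)


class TestDualScale:
    def test_hand_computed_2x2(self):
        m = ExpressionMatrix(pd.DataFrame([[0.0, 2.0], [2.0, 0.0]],
                                          columns=["a", "b"]), "arcsinh")
        out = dual_scale(m).values
        np.testing.assert_allclose(out, [[-1.0, 1.0], [1.0, -1.0]], atol=1e-12)

    def test_constant_column_maps_to_zero_and_rows_centred(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        df["const"] = 3.14
        out = dual_scale(ExpressionMatrix(df, "arcsinh")).values
        assert np.abs(out.mean(axis=1)).max() < 1e-10

    def test_pass1_invariant_to_affine_column_transform(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        df2 = df.copy()
        df2["b"] = 5.0 * df2["b"] - 7.0
        out1 = dual_scale(ExpressionMatrix(df, "arcsinh")).values
        out2 = dual_scale(ExpressionMatrix(df2, "arcsinh")).values
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_single_cell_degenerates_to_zeros(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], columns=["a", "b"]),
                             "arcsinh")
        np.testing.assert_array_equal(dual_scale(m).values, [[0.0, 0.0]])


class TestClustering:
    def _blobs(self, n=200, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, (n // 2, 3)),
                            rng.normal(sep, 1, (n - n // 2, 3))])
        truth = np.repeat([0, 1], [n // 2, n - n // 2])
        m = ExpressionMatrix(pd.DataFrame(x, columns=list("abc")), "scaled")
        return m, truth

    def test_two_separated_blobs_recovered_exactly(self):
        # resolution low enough that Leiden does not shatter 100-cell
        # communities of the k-NN graph
        m, truth = self._blobs()
        labels = cluster_cells(m, k=20, resolution=0.3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_rows_form_one_cluster(self):
        m = ExpressionMatrix(pd.DataFrame(np.ones((30, 3)),
                                          columns=list("abc")), "scaled")
        assert set(cluster_cells(m, k=5, resolution=2.0, seed=0)) == {0}

    def test_seeded_determinism(self):
        m, _ = self._blobs(seed=4)
        l1 = cluster_cells(m, k=10, resolution=2.0, seed=7)
        l2 = cluster_cells(m, k=10, resolution=2.0, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_cells_raises(self):
        m, _ = self._blobs(n=10)
        with pytest.raises(ValueError):
            cluster_cells(m, k=30, resolution=2.0, seed=0)


class TestAnnotation:
    def _matrix(self, rows):
        cols = ["PanCK", "CD20", "CD3e", "CD8", "CD68", "isPLA",
                "nuclear_area"]
        return ExpressionMatrix(pd.DataFrame(rows, columns=cols), "arcsinh")

    def test_dominant_marker_wins(self):
        base = [0.1, 0.1, 0.1, 0.1, 0.1, 0.0, 0.5]
        b_cell = [0.1, 3.0, 0.1, 0.1, 0.1, 0.0, 0.5]
        m = self._matrix([base] * 10 + [b_cell] * 10)
        labels = np.repeat([0, 1], 10)
        res = annotate_clusters(labels, m)
        assert set(res.cell_type[10:]) == {"B cell"}

    def test_all_equal_zscores_fall_back_to_precedence(self):
        m = self._matrix([[1.0] * 7, [0.0] * 7] * 5)
        labels = np.tile([0, 1], 5)
        res = annotate_clusters(labels, m)
        # both clusters symmetric in every marker -> precedence gives Tumour
        assert set(res.cell_type) == {"Tumour"}

    def test_cd8_cluster_annotated_over_cd3(self):
        # co-expression profile of cytotoxic T cells: CD3e and CD8 both high
        other = [0.1, 0.1, 0.1, 0.1, 0.1, 0.0, 0.5]
        cd8 = [0.1, 0.1, 2.0, 2.5, 0.1, 0.0, 0.5]
        m = self._matrix([other] * 20 + [cd8] * 10)
        labels = np.repeat([0, 1], [20, 10])
        res = annotate_clusters(labels, m)
        assert set(res.cell_type[20:]) == {"CD8 T cell"}


def test_phenotype_recovery_on_synthetic_tissue(default_cfg):
    """The full QC -> transform -> cluster -> annotate chain recovers the
    generator's planted cell types."""
    tables, _, truths = pl.generate_cohort({"CR": 1, "PD": 1}, seed=7)
    labelled, result, reports = pl.phenotype_cells(tables, default_cfg)
    for t, gt, rep in zip(labelled, truths, reports):
        m = t.df.merge(gt.cells, on="cell_id")
        assert (m["cell_type"] == m["true_type"]).mean() >= 0.90
        assert adjusted_rand_score(m["true_type"], m["cell_type"]) >= 0.8
        assert rep.n_retained == len(t)
    # every cluster annotated to exactly one type
    assert result.annotation["cell_type"].isin(pl.CELL_TYPES).all()
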