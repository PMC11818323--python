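"""k-NN windows, window compositions, KMeans CN fitting and Kneedle."""

import numpy as np
import pandas as pd
import pytest

import plaspace as pl
from plaspace.neighborhoods import (fit_cn, knn_windows, select_k_kneedle,
                                    window_composition)


class TestKnnWindows:
    def test_collinear_hand_geometry(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [25.0, 0.0]])
        win = knn_windows(xy, k=1, include_self=False)
        assert win.tolist() == [[1], [0], [1]]

    def test_window_includes_self_first(self):
        xy = np.random.default_rng(0).uniform(0, 100, (30, 2))
        win = knn_windows(xy, k=5, include_self=True)
        assert win.shape == (30, 6)
        np.testing.assert_array_equal(win[:, 0], np.arange(30))

    def test_duplicate_coordinates_tie_break_by_index(self):
        xy = np.zeros((5, 2))
        win = knn_windows(xy, k=2, include_self=False)
        for i in range(5):
            expected = [j for j in range(5) if j != i][:2]
            assert win[i].tolist() == expected

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, (500, 2))
        for k in (10, 100):
            win = knn_windows(xy, k=k, include_self=False)
            d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            brute = np.argsort(d2, axis=1)[:, :k]
            # compare as sets: ordering differs only on exact ties,
            # absent for continuous uniforms
            assert all(set(win[i]) == set(brute[i]) for i in range(500))

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            knn_windows(np.zeros((5, 2)), k=5)


class TestComposition:
    def test_pure_window_is_one_hot(self):
        win = np.arange(11)[None, :]
        comp = window_composition(win, ["Tumour"] * 11,
                                  pl.CELL_TYPES)
        expected = np.zeros(len(pl.CELL_TYPES))
        expected[pl.CELL_TYPES.index("Tumour")] = 1.0
        np.testing.assert_allclose(comp[0], expected)

    def test_mixed_window_fractions(self):
        labels = ["Tumour"] * 6 + ["Macrophage"] * 5
        comp = window_composition(np.arange(11)[None, :], labels,
                                  pl.CELL_TYPES)
        assert comp[0][pl.CELL_TYPES.index("Tumour")] == pytest.approx(6 / 11)
        assert comp[0][pl.CELL_TYPES.index("Macrophage")] == pytest.approx(5 / 11)

    def test_rows_on_simplex(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 200, (150, 2))
        labels = rng.choice(pl.CELL_TYPES, 150)
        win = knn_windows(xy, k=10)
        comp = window_composition(win, labels, pl.CELL_TYPES)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-12)
        assert (comp >= 0).all()

    def test_label_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            window_composition(np.array([[0, 1]]), ["Tumour", "Alien"],
                               pl.CELL_TYPES)


class TestFitCN:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(3)
        comp = rng.dirichlet(np.ones(4), 50)
        centroids, labels, inertia = fit_cn(comp, K=1, seed=0)
        np.testing.assert_allclose(centroids[0], comp.mean(axis=0), atol=1e-12)
        assert inertia == pytest.approx(((comp - comp.mean(0)) ** 2).sum())

    def test_separable_one_hot_groups(self):
        comp = np.array([[1.0, 0.0]] * 20 + [[0.0, 1.0]] * 20)
        _, labels, inertia = fit_cn(comp, K=2, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_inertia_self_consistent(self):
        rng = np.random.default_rng(4)
        comp = rng.dirichlet(np.ones(5), 300)
        centroids, labels, inertia = fit_cn(comp, K=4, seed=1)
        recomputed = sum(((comp[labels == j] - centroids[j]) ** 2).sum()
                         for j in range(4))
        assert inertia == pytest.approx(recomputed, abs=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        comp = rng.dirichlet(np.ones(3), 200)
        a = fit_cn(comp, K=3, seed=9)
        b = fit_cn(comp, K=3, seed=9)
        np.testing.assert_array_equal(a[1], b[1])


class TestKneedle:
    def test_constructed_elbow(self):
        ks = range(3, 16)
        curve = {k: (10.0 * (6 - k) + 0.9 if k <= 6 else 0.9 - 0.1 * (k - 6))
                 for k in ks}
        assert select_k_kneedle(curve) == 6

    def test_exponential_decay_matches_definition_oracle(self):
        ks = np.arange(3, 16)
        ys = 2.0 ** (-ks.astype(float))
        # independent transcription of the definition: normalise, invert,
        # maximise distance to the diagonal
        x_n = (ks - ks[0]) / (ks[-1] - ks[0])
        y_n = (ys - ys.min()) / (ys.max() - ys.min())
        expected = int(ks[np.argmax((1 - y_n) - x_n)])
        assert select_k_kneedle(dict(zip(ks.tolist(), ys))) == expected

    def test_flat_curve_falls_back_to_smallest_k(self):
        assert select_k_kneedle({k: 5.0 for k in range(3, 16)}) == 3

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            select_k_kneedle({k: float(k) for k in range(3, 16)})


class TestModel:
    def test_assign_writes_nearest_centroid_labels(self, typed_cohort,
                                                   default_cfg):
        tables, _, _ = typed_cohort
        model = pl.fit_neighbourhoods(tables, default_cfg, variant="plain",
                                      K=4)
        out = pl.assign_cn(model, tables[0])
        assert "cn_label" in out.df.columns
        assert set(out.df["cn_label"]) <= set(range(4))

    def test_inertia_curve_non_increasing(self, typed_cohort, default_cfg):
        tables, _, _ = typed_cohort
        model = pl.fit_neighbourhoods(tables, default_cfg, variant="plain")
        ks = sorted(model.inertia_curve)
        vals = [model.inertia_curve[k] for k in ks]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert model.selected_K in ks

    def test_centroid_permutation_equivariance(self, typed_cohort,
                                               default_cfg):
        tables, _, _ = typed_cohort
        model = pl.fit_neighbourhoods(tables, default_cfg, variant="plain",
                                      K=3)
        perm = np.array([2, 0, 1])
        import dataclasses
        permuted = dataclasses.replace(model, centroids=model.centroids[perm])
        a = pl.assign_cn(model, tables[0]).df["cn_label"].to_numpy()
        b = pl.assign_cn(permuted, tables[0]).df["cn_label"].to_numpy()
        inv = np.argsort(perm)
        np.testing.assert_array_equal(inv[a], b)

    def test_rigid_motion_leaves_compositions_unchanged(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 300, (200, 2))
        labels = rng.choice(pl.CELL_TYPES, 200)
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy2 = xy @ rot.T + 40.0
        c1 = window_composition(knn_windows(xy, 10), labels, pl.CELL_TYPES)
        c2 = window_composition(knn_windows(xy2, 10), labels, pl.CELL_TYPES)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_json_round_trip(self, typed_cohort, default_cfg):
        tables, _, _ = typed_cohort
        model = pl.fit_neighbourhoods(tables, default_cfg, variant="plain",
                                      K=3)
        back = pl.NeighbourhoodModel.from_json(model.to_json())
        np.testing.assert_allclose(back.centroids, model.centroids)
        assert back.inertia_curve == model.inertia_curve
        assert back.selected_K == model.selected_K

    def test_augmented_alphabet_and_labels(self, typed_cohort, default_cfg):
        tables, _, _ = typed_cohort
        t = pl.attach_ispla(tables[0], pl.classify_ispla(tables[0]))
        labels = pl.augmented_labels(t.df)
        assert set(labels) <= set(pl.augmented_alphabet())
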