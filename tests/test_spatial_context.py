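"""Minimal CN combinations, SC maps and barycentric projections."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plaspace as pl
from plaspace.spatial_context import (_TRIANGLE, barycentric_projection,
                                      build_scm_graph, combination_key,
                                      minimal_combination, sc_windows)


def _exhaustive_minimal(freq, threshold):
    """Definition-level oracle: try every abundance-ordered prefix length."""
    ids = np.arange(len(freq))
    order = sorted(ids, key=lambda i: (-freq[i], i))
    for L in range(1, len(freq) + 1):
        if sum(freq[i] for i in order[:L]) > threshold:
            return tuple(sorted(order[:L]))
    return tuple(sorted(order))


class TestMinimalCombination:
    @pytest.mark.parametrize("freq,expected", [
        ((0.95, 0.05, 0.0), (0,)),
        ((0.50, 0.45, 0.05), (0, 1)),
        ((0.40, 0.35, 0.25), (0, 1, 2)),
    ])
    def test_forced_cases(self, freq, expected):
        assert minimal_combination(np.array(freq), 0.90) == expected

    def test_strictly_greater_than_rule(self):
        # exactly 90% does not stop the recursion
        assert minimal_combination(np.array([0.90, 0.10]), 0.90) == (0, 1)

    def test_ties_broken_by_ascending_id(self):
        # ids 0 and 2 tie at 0.3; the lower id joins the prefix
        assert minimal_combination(np.array([0.3, 0.4, 0.3]), 0.65) == (0, 1)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            freq = rng.dirichlet(np.ones(rng.integers(2, 8)))
            t = rng.uniform(0.5, 0.99)
            got = minimal_combination(freq, t)
            assert got == _exhaustive_minimal(freq, t)
            # minimality: the prefix without its least-abundant member
            # no longer exceeds the threshold
            if len(got) > 1:
                members = sorted(got, key=lambda i: (-freq[i], i))
                assert sum(freq[i] for i in members[:-1]) <= t

    def test_invariant_to_appended_zero_frequency_cns(self):
        freq = np.array([0.6, 0.4])
        padded = np.concatenate([freq, np.zeros(5)])
        assert (minimal_combination(freq, 0.9)
                == minimal_combination(padded, 0.9))

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            minimal_combination(np.zeros(4), 0.9)

    @settings(max_examples=200, derandomize=True)
    @given(weights=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8),
           threshold=st.floats(0.05, 0.95))
    def test_property_prefix_is_minimal_and_sufficient(self, weights,
                                                       threshold):
        freq = np.array(weights) / np.sum(weights)
        got = minimal_combination(freq, threshold)
        assert got == _exhaustive_minimal(freq, threshold)
        assert sum(freq[list(got)]) > threshold
        ordered = sorted(got, key=lambda i: (-freq[i], i))
        assert sum(freq[i] for i in ordered[:-1]) <= threshold


class TestScWindows:
    def test_pure_region_is_one_hot(self):
        rng = np.random.default_rng(1)
        t = pl.CellTable("T", _cells(rng.uniform(0, 100, (150, 2))))
        t = t.with_column("cn_label_pla", np.zeros(150, dtype=int))
        f = sc_windows(t, k=100, n_cn=3)
        np.testing.assert_allclose(f[:, 0], 1.0)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 300, (300, 2))
        t = pl.CellTable("T", _cells(xy))
        labels = rng.integers(0, 4, 300)
        t = t.with_column("cn_label_pla", labels)
        f = sc_windows(t, k=100, n_cn=4)
        d2 = ((xy[:, None] - xy[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(0, 300, 37):
            members = np.argsort(d2[i])[:100].tolist() + [i]
            counts = np.bincount(labels[members], minlength=4) / 101
            np.testing.assert_allclose(f[i], counts, atol=1e-12)


def _cells(xy):
    df = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(xy))],
                       "x": xy[:, 0], "y": xy[:, 1],
                       "nuclear_area": 50.0})
    for c in pl.CHANNELS:
        df[c] = 1.0
    return df


class TestSCMGraph:
    def test_single_combination_single_node(self):
        g = build_scm_graph(["0"] * 100)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0
        assert g.nodes["0"]["fraction"] == 1.0

    def test_subset_edge_rule(self):
        combos = ["0"] * 40 + ["1"] * 40 + ["0+1"] * 20
        g = build_scm_graph(combos)
        assert set(g.edges) == {("0", "0+1"), ("1", "0+1")}

    def test_edges_increase_size_by_one_only(self):
        combos = ["0"] * 30 + ["0+1+2"] * 30 + ["0+1"] * 30
        g = build_scm_graph(combos)
        assert ("0", "0+1+2") not in g.edges
        assert ("0+1", "0+1+2") in g.edges

    def test_min_fraction_floor(self):
        combos = ["0"] * 9999 + ["1+2"]
        g = build_scm_graph(combos, min_fraction=1e-3)
        assert set(g.nodes) == {"0"}

    def test_random_graphs_are_dags(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            combos = [combination_key(tuple(sorted(
                rng.choice(5, size=rng.integers(1, 4), replace=False))))
                for _ in range(50)]
            assert nx.is_directed_acyclic_graph(build_scm_graph(combos))


class TestBarycentric:
    def _proj(self, freqs, purity=0.9995):
        n = len(freqs)
        t = pl.CellTable("T", _cells(np.zeros((n, 2))))
        t = t.with_column("cn_label_pla", np.zeros(n, dtype=int))
        return barycentric_projection(np.asarray(freqs), t, (0, 1, 2),
                                      purity=purity)

    def test_pure_window_maps_to_vertex(self):
        p = self._proj([[1.0, 0.0, 0.0]])
        np.testing.assert_allclose(p.df[["u", "v"]].iloc[0], _TRIANGLE[0])

    def test_even_pair_maps_to_edge_midpoint(self):
        p = self._proj([[0.5, 0.5, 0.0]])
        np.testing.assert_allclose(p.df[["u", "v"]].iloc[0],
                                   (_TRIANGLE[0] + _TRIANGLE[1]) / 2)

    def test_uniform_window_maps_to_centroid(self):
        p = self._proj([[1 / 3, 1 / 3, 1 / 3]])
        np.testing.assert_allclose(p.df[["u", "v"]].iloc[0],
                                   _TRIANGLE.mean(axis=0), atol=1e-12)

    def test_purity_filter_and_weights(self):
        freqs = [[0.999, 0.0005, 0.0005],      # qualifies at 99.95%
                 [0.5, 0.3, 0.1]]              # 90% on triple: filtered out
        p = self._proj(freqs)
        assert len(p.df) == 1
        w = p.df[["w0", "w1", "w2"]].to_numpy()
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_no_qualifying_windows_flagged(self):
        p = self._proj([[0.4, 0.3, 0.1]])
        assert p.flagged and len(p.df) == 0

    def test_duplicate_triple_rejected(self):
        t = pl.CellTable("T", _cells(np.zeros((1, 2))))
        t = t.with_column("cn_label_pla", [0])
        with pytest.raises(ValueError, match="distinct"):
            barycentric_projection(np.array([[1.0, 0.0, 0.0]]), t, (0, 0, 1))


def test_interface_fraction_counts_tumour_macrophage_contexts(typed_cohort,
                                                              default_cfg):
    tables, _, _ = typed_cohort
    model = pl.fit_neighbourhoods(tables, default_cfg, variant="plain")
    combos = []
    for t in tables:
        t = pl.assign_cn(model, t)
        t2, _ = pl.assign_spatial_context(t, default_cfg, cn_col="cn_label",
                                          n_cn=model.K)
        combos.extend(t2.df["sc_combination"])
    frac = pl.tumour_macrophage_interface_fraction(combos, model)
    assert 0.0 <= frac <= 1.0
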