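"""Centrality descriptors, HITS, assortativity, rankings."""

import numpy as np
import pandas as pd
import pytest

from omiclayers.core import Layer, build_multilayer, supra_structure
from omiclayers.diagnostics import (
    degree,
    diagnostics_table,
    hits,
    interlayer_assortativity,
    multilayer_descriptor,
    multilayer_hits,
    strength,
    top_k,
)

from conftest import random_layer, random_multilayer


def triangle():
    return Layer.from_edges("L", [
        ("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
    ])


class TestDegreeStrength:
    def test_triangle_degrees(self):
        assert degree(triangle()) == {"A": 2, "B": 2, "C": 2}

    def test_isolated_node_zero(self):
        layer = Layer.from_edges("L", [("A", "B", 1.0)], nodes=["Z"])
        assert degree(layer)["Z"] == 0
        assert strength(layer)["Z"] == 0.0

    def test_strength_sums_incident_weights(self):
        layer = Layer.from_edges("L", [("A", "B", 0.5), ("A", "C", 0.25)])
        assert strength(layer)["A"] == pytest.approx(0.75)

    def test_unit_weights_make_strength_equal_degree(self, rng):
        genes = [f"G{i}" for i in range(10)]
        layer = Layer("L")
        for g in genes:
            layer.add_node(g)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < 0.4:
                    layer.add_edge(genes[i], genes[j], 1.0)
        d, s = degree(layer), strength(layer)
        assert all(s[g] == pytest.approx(d[g]) for g in genes)

    @pytest.mark.parametrize("seed", range(5))
    def test_handshake_identities_and_adjacency_scan(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_layer(rng, "L", [f"G{i}" for i in range(30)],
                             density=0.2)
        d, s = degree(layer), strength(layer)
        assert sum(d.values()) == 2 * layer.n_edges
        total_w = sum(layer.weight(u, v) for u, v in layer.edges)
        assert sum(s.values()) == pytest.approx(2 * total_w)
        # oracle: per-node neighbor enumeration on the dense adjacency
        genes = layer.sorted_nodes()
        A = layer.adjacency(genes)
        for i, g in enumerate(genes):
            assert d[g] == int((A[i] > 0).sum())
            assert s[g] == pytest.approx(A[i].sum())


class TestMultilayerDescriptor:
    def test_sums_per_layer_contributions(self):
        la = Layer.from_edges("a", [("A", "B", 1.0), ("A", "C", 1.0)])
        lb = Layer.from_edges("b", [], nodes=["A"])
        lc = Layer.from_edges("c", [("A", "B", 1.0), ("A", "C", 1.0),
                                    ("A", "D", 1.0)])
        M = build_multilayer([la, lb, lc])
        assert multilayer_descriptor(M, "degree")["A"] == 5

    def test_single_layer_reduces_to_layer_metric(self, rng):
        layer = random_layer(rng, "L", [f"G{i}" for i in range(8)])
        M = build_multilayer([layer])
        assert multilayer_descriptor(M, "degree") == degree(layer)

    def test_matches_per_layer_recomputation_oracle(self, rng):
        M = random_multilayer(rng, n_layers=3, n_genes=12, presence=0.7)
        got = multilayer_descriptor(M, "strength")
        for g in M.gene_universe:
            expected = sum(strength(ly).get(g, 0.0) for ly in M.layers)
            assert got[g] == pytest.approx(expected)

    def test_couplings_add_to_descriptors_when_included(self):
        la = Layer.from_edges("a", [("A", "B", 1.0)])
        lb = Layer.from_edges("b", [], nodes=["A"])
        M = build_multilayer([la, lb], coupling_weight=0.5)
        assert multilayer_descriptor(M, "degree")["A"] == 1
        assert multilayer_descriptor(
            M, "degree", include_couplings=True)["A"] == 3
        assert multilayer_descriptor(
            M, "strength", include_couplings=True)["A"] == pytest.approx(2.0)

    def test_equals_aggregate_degree_only_without_cooccurring_pairs(self):
        # no gene pair shared between layers: the sums coincide
        la = Layer.from_edges("a", [("A", "B", 1.0)])
        lb = Layer.from_edges("b", [("C", "D", 1.0)])
        M = build_multilayer([la, lb])
        from omiclayers.core import aggregate_layer
        agg_deg = degree(aggregate_layer(M))
        assert multilayer_descriptor(M, "degree") == agg_deg
        # a pair in both layers collapses to one aggregate edge
        lc = Layer.from_edges("c", [("A", "B", 1.0)])
        ld = Layer.from_edges("d", [("A", "B", 1.0)])
        M2 = build_multilayer([lc, ld])
        assert multilayer_descriptor(M2, "degree")["A"] == 2
        assert degree(aggregate_layer(M2))["A"] == 1


class TestHits:
    def test_two_node_edge_scores(self):
        layer = Layer.from_edges("L", [("A", "B", 1.0)])
        res = hits(layer)
        assert res.hub["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert res.hub["B"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_star_graph_scores(self):
        # oracle: principal eigenvector of the 5x5 star adjacency has
        # center 1/sqrt(2) and leaves 1/(2*sqrt(2)) ~ 0.35355
        layer = Layer.from_edges("L", [
            ("C", f"L{i}", 1.0) for i in range(4)
        ])
        res = hits(layer)
        assert res.hub["C"] == pytest.approx(0.70711, abs=1e-5)
        for i in range(4):
            assert res.hub[f"L{i}"] == pytest.approx(0.35355, abs=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_hub_equals_authority_on_undirected(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_layer(rng, "L", [f"G{i}" for i in range(7)],
                             density=0.5)
        if layer.n_edges == 0:
            layer.add_edge("G0", "G1", 0.5)
        res = hits(layer, tol=1e-12)
        for g in res.hub:
            assert res.hub[g] == pytest.approx(res.authority[g], abs=1e-9)

    def test_unit_norm_and_nonnegative(self, rng):
        layer = random_layer(rng, "L", [f"G{i}" for i in range(10)],
                             density=0.4)
        res = hits(layer)
        v = np.array(list(res.hub.values()))
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert (v >= 0).all()

    def test_edgeless_structure_warns_with_zero_scores(self):
        layer = Layer.from_edges("L", [], nodes=["A", "B"])
        with pytest.warns(UserWarning, match="edgeless"):
            res = hits(layer)
        assert set(res.hub.values()) == {0.0}

    def test_nonconvergence_is_flagged(self):
        layer = Layer.from_edges("L", [("A", "B", 1.0), ("C", "D", 0.3)])
        with pytest.warns(UserWarning, match="did not converge"):
            res = hits(layer, tol=1e-15, max_iter=2)
        assert not res.converged

    def test_supra_structure_hits_matches_dense_eigenvector(self, rng):
        M = random_multilayer(rng, n_layers=2, n_genes=5, presence=1.0,
                              density=0.6)
        S = supra_structure(M)
        res = hits(S, tol=1e-12)
        w, V = np.linalg.eigh(S.matrix)
        lead = np.abs(V[:, np.argmax(w)])
        got = np.array([res.hub[k] for k in S.ordering])
        np.testing.assert_allclose(got, lead, atol=1e-6)

    def test_multilayer_gene_scores_have_unit_norm(self, rng):
        M = random_multilayer(rng, n_layers=3, n_genes=8, presence=0.8)
        res = multilayer_hits(M)
        v = np.array(list(res.hub.values()))
        assert np.linalg.norm(v) == pytest.approx(1.0)


class TestAssortativity:
    def identical_pair(self, rng):
        genes = [f"G{i}" for i in range(10)]
        la = random_layer(rng, "a", genes, density=0.4)
        lb = la.copy()
        lb.name = "b"
        return build_multilayer([la, lb])

    def test_identical_layers_correlate_at_one(self, rng):
        M = self.identical_pair(rng)
        for metric in ("degree", "strength"):
            for method in ("pearson", "spearman"):
                A = interlayer_assortativity(M, metric, method)
                assert A.values[0, 1] == pytest.approx(1.0)
                np.testing.assert_allclose(np.diag(A.values), 1.0)

    def test_reversed_degrees_give_minus_one(self):
        # degree vectors (1, 2, 3, 2) and (3, 2, 1, 2): y = 4 - x, an
        # exact linear reversal, so Pearson is exactly -1
        la = Layer.from_edges("a", [("B", "C", 1.0), ("C", "A", 1.0),
                                    ("C", "E", 1.0), ("B", "E", 1.0)])
        lb = Layer.from_edges("b", [("B", "A", 1.0), ("A", "C", 1.0),
                                    ("A", "E", 1.0), ("B", "E", 1.0)])
        M = build_multilayer([la, lb])
        for method in ("pearson", "spearman"):
            A = interlayer_assortativity(M, "degree", method)
            assert A.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula_oracle(self, rng):
        M = random_multilayer(rng, n_layers=2, n_genes=15, presence=0.8)
        A = interlayer_assortativity(M, "strength", "pearson")
        genes = sorted(M.layers[0].nodes | M.layers[1].nodes)
        x = np.array([strength(M.layers[0]).get(g, 0.0) for g in genes])
        y = np.array([strength(M.layers[1]).get(g, 0.0) for g in genes])
        # explicit sum formula
        n = len(genes)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x ** 2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y ** 2).sum() - y.sum() ** 2
        )
        assert A.values[0, 1] == pytest.approx(num / den)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        # layer b is a star with distinct edge weights: cubing every
        # weight transforms the strength vector monotonically (leaf
        # strengths are the weights themselves; the hub keeps the
        # largest strength), so Spearman entries are unchanged while
        # Pearson entries move
        genes = ["HUB"] + [f"G{i}" for i in range(8)]
        la = random_layer(rng, "a", genes, density=0.5)
        weights = rng.uniform(0.2, 0.9, size=8)

        def star(name, ws):
            layer = Layer(name)
            for g in genes:
                layer.add_node(g)
            for i, w in enumerate(ws):
                layer.add_edge("HUB", f"G{i}", w)
            return layer

        M1 = build_multilayer([la, star("b", weights)])
        M2 = build_multilayer([la, star("b", weights ** 3)])
        s1 = interlayer_assortativity(M1, "strength", "spearman")
        s2 = interlayer_assortativity(M2, "strength", "spearman")
        p1 = interlayer_assortativity(M1, "strength", "pearson")
        p2 = interlayer_assortativity(M2, "strength", "pearson")
        assert s1.values[0, 1] == pytest.approx(s2.values[0, 1], abs=1e-12)
        assert abs(p1.values[0, 1] - p2.values[0, 1]) > 1e-6

    def test_zero_variance_reported_as_missing(self):
        la = Layer.from_edges("a", [("A", "B", 1.0), ("B", "C", 1.0),
                                    ("C", "A", 1.0)])
        lb = Layer.from_edges("b", [("A", "B", 1.0)], nodes=["C"])
        M = build_multilayer([la, lb])
        A = interlayer_assortativity(M, "degree", "pearson")
        assert np.isnan(A.values[0, 1])

    def test_intersection_alignment_flag(self):
        la = Layer.from_edges("a", [("A", "B", 1.0), ("B", "C", 1.0)])
        lb = Layer.from_edges("b", [("A", "B", 1.0), ("A", "D", 1.0)])
        M = build_multilayer([la, lb])
        union = interlayer_assortativity(M, "degree", "pearson")
        inter = interlayer_assortativity(M, "degree", "pearson",
                                         alignment="intersection")
        assert union.values[0, 1] != pytest.approx(inter.values[0, 1])


class TestDiagnosticsTableAndTopK:
    def test_scopes_and_unit_norms(self, rng):
        M = random_multilayer(rng, n_layers=2, n_genes=8, presence=0.9,
                              density=0.5)
        table = diagnostics_table(M)
        scopes = set(table["scope"])
        assert scopes == {"L0", "L1", "aggregate", "multilayer"}
        for scope in scopes:
            v = table.loc[table["scope"] == scope, "hub"].to_numpy()
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-6)

    def test_multilayer_rows_are_layer_sums(self, rng):
        M = random_multilayer(rng, n_layers=3, n_genes=8, presence=0.7)
        table = diagnostics_table(M)
        ml = table[table["scope"] == "multilayer"].set_index("gene")
        for g in M.gene_universe:
            expected = sum(degree(ly).get(g, 0) for ly in M.layers)
            assert ml.loc[g, "degree"] == expected

    def test_top_k_tie_break_is_lexicographic(self):
        table = pd.DataFrame({
            "gene": ["A", "B", "C"],
            "scope": ["L"] * 3,
            "degree": [3, 1, 3],
            "strength": [1.0, 1.0, 1.0],
            "hub": [0.0] * 3,
            "authority": [0.0] * 3,
        })
        assert top_k(table, "degree", "L", k=2) == ["A", "C"]

    def test_top_k_truncates_to_gene_count(self):
        table = pd.DataFrame({
            "gene": ["B", "A"], "scope": ["L"] * 2,
            "degree": [1, 2], "strength": [0.0] * 2,
            "hub": [0.0] * 2, "authority": [0.0] * 2,
        })
        assert top_k(table, "degree", "L", k=10) == ["A", "B"]

    def test_top_k_matches_full_sort_oracle(self, rng):
        genes = [f"G{i:02d}" for i in range(25)]
        vals = rng.integers(0, 5, size=25)
        table = pd.DataFrame({
            "gene": genes, "scope": ["L"] * 25,
            "degree": vals, "strength": vals.astype(float),
            "hub": np.zeros(25), "authority": np.zeros(25),
        })
        expected = [
            g for _, g in sorted(
                zip(vals, genes), key=lambda t: (-t[0], t[1])
            )
        ][:20]
        assert top_k(table, "degree", "L", k=20) == expected
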