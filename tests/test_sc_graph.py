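"""Pseudo-bulk aggregation, patient graphs, and edge-featured attention."""

import numpy as np
import pytest

from icipred.core_data import (CellAnnotationTable, ExpressionMatrix,
                               ValidationError)
from icipred.encoders import MLPStack
from icipred.pathway import PathwayScoreMatrix
from icipred.sc_graph import (GraphAttentionParams, PatientGraph,
                              assemble_patient_graph, celltype_activity,
                              gatv2_layer, graph_readout,
                              pseudobulk_matrix, pseudobulk_profiles)
from icipred.ssn import EdgeRecord, SampleNetwork


def _counts(values, samples_per_cell):
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    m = ExpressionMatrix(genes, cells, values)
    ann = CellAnnotationTable(
        {c: sp for c, sp in zip(cells, samples_per_cell)})
    return m, ann


class TestPseudoBulk:
    def test_one_cell_per_type_means_equal_cells(self, rng):
        vals = rng.standard_normal((4, 2))
        m, ann = _counts(vals, [("p1", "B"), ("p1", "NK")])
        prof = pseudobulk_profiles(m, ann)["p1"]
        assert prof.cell_types == ["B", "NK"]
        np.testing.assert_array_equal(prof.means[0], vals[:, 0])
        np.testing.assert_array_equal(prof.means[1], vals[:, 1])

    def test_proportions_from_counts(self, rng):
        vals = rng.standard_normal((3, 6))
        assign = [("p1", "B")] * 4 + [("p1", "NK")] * 2
        m, ann = _counts(vals, assign)
        prof = pseudobulk_profiles(m, ann)["p1"]
        np.testing.assert_allclose(prof.proportions, [2 / 3, 1 / 3])

    def test_group_mean_oracle(self, rng):
        vals = rng.standard_normal((5, 50))
        types = rng.choice(["B", "NK", "CD4T"], size=50)
        assign = [("p1", t) for t in types]
        m, ann = _counts(vals, assign)
        prof = pseudobulk_profiles(m, ann)["p1"]
        for t, mean_row in zip(prof.cell_types, prof.means):
            np.testing.assert_allclose(
                mean_row, vals[:, types == t].mean(axis=1))

    def test_proportions_sum_to_one(self, small_sc_prep):
        for prof in small_sc_prep.profiles.values():
            assert prof.proportions.sum() == pytest.approx(1.0)


class TestActivity:
    def _profile(self, vals):
        from icipred.sc_graph import PseudoBulkProfile
        return PseudoBulkProfile("p", [f"g{i}" for i in range(vals.shape[1])],
                                 ["B"], vals, np.array([3]))

    def test_single_gene_panel_is_zscored_value(self, rng):
        vals = rng.standard_normal((1, 6))
        prof = self._profile(vals)
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        assert celltype_activity(prof, "B", ["g2"]) == pytest.approx(z[2])

    def test_constant_profile_activity_zero(self):
        prof = self._profile(np.zeros((1, 5)))
        assert celltype_activity(prof, "B", ["g0", "g1"]) == 0.0

    def test_matches_direct_mean(self, rng):
        vals = rng.standard_normal((1, 8))
        prof = self._profile(vals)
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        panel = ["g1", "g4", "g6"]
        assert celltype_activity(prof, "B", panel) == pytest.approx(
            z[[1, 4, 6]].mean())

    def test_empty_panel_intersection_errors(self, rng):
        prof = self._profile(rng.standard_normal((1, 4)))
        with pytest.raises(ValidationError):
            celltype_activity(prof, "B", ["missing"])


def _toy_network(types, kept_pairs):
    edges = [EdgeRecord(a, b, 0.1, 0.2, 0.5, 2.5, 0.01, True)
             for a, b in kept_pairs]
    return SampleNetwork("p1", list(types), edges, 0.05, "leave_out")


class TestGraphAssembly:
    def _setup(self, rng, types=("B", "NK")):
        vals = rng.standard_normal((6, len(types) * 2))
        assign = []
        for t in types:
            assign += [("p1", t)] * 2
        m, ann = _counts(vals, assign)
        prof = pseudobulk_profiles(m, ann)["p1"]
        stack = MLPStack.init([6, 3], rng)
        pstack = MLPStack.init([2, 3], rng)
        cols = [f"p1::{t}" for t in types]
        scores = PathwayScoreMatrix(["s1", "s2"], cols,
                                    rng.uniform(-1, 1, (2, len(types))))
        return prof, stack, pstack, scores

    def test_two_types_one_edge(self, rng):
        prof, stack, pstack, scores = self._setup(rng)
        net = _toy_network(["B", "NK"], [("B", "NK")])
        g = assemble_patient_graph(prof, stack, pstack, scores, net)
        assert g.node_names == ["B", "NK"]
        assert g.adjacency.sum() == 4  # 2 self-loops + 1 undirected edge
        assert g.edge_features[0, 1] == 0.5

    def test_no_kept_edges_still_valid(self, rng):
        prof, stack, pstack, scores = self._setup(rng)
        net = _toy_network(["B", "NK"], [])
        g = assemble_patient_graph(prof, stack, pstack, scores, net)
        np.testing.assert_array_equal(g.adjacency, np.eye(2, dtype=bool))
        out, alpha = gatv2_layer(g, GraphAttentionParams.init(
            g.node_features.shape[1], 2, 4, rng))
        assert np.all(np.isfinite(out))

    def test_kept_edges_match_network(self, small_sc_prep):
        """Cross-module consistency: tensor edges equal the networks' kept
        lists."""
        ds = small_sc_prep.dataset
        tidx = {t: i for i, t in enumerate(ds.cell_types)}
        for i, pid in enumerate(ds.sample_ids):
            kept = {(tidx[e.var_i], tidx[e.var_j])
                    for e in small_sc_prep.networks[pid].edges
                    if e.kept and ds.node_mask[i, tidx[e.var_i]]
                    and ds.node_mask[i, tidx[e.var_j]]}
            off_diag = {(a, b) for a, b in zip(*np.nonzero(ds.adjacency[i]))
                        if a < b}
            assert off_diag == {(min(a, b), max(a, b)) for a, b in kept}

    def test_json_round_trip_fields(self, rng):
        import json
        prof, stack, pstack, scores = self._setup(rng)
        net = _toy_network(["B", "NK"], [("B", "NK")])
        g = assemble_patient_graph(prof, stack, pstack, scores, net)
        payload = json.loads(g.to_json())
        assert [n["name"] for n in payload["nodes"]] == ["B", "NK"]
        assert payload["edges"] == [{"i": "B", "j": "NK", "weight": 0.5}]


class TestGraphAttention:
    def _graph(self, rng, n=3, F=5, edges=((0, 1), (1, 2))):
        X = rng.standard_normal((n, F))
        E = np.eye(n)
        adj = np.eye(n, dtype=bool)
        for a, b in edges:
            E[a, b] = E[b, a] = rng.uniform(-1, 1)
            adj[a, b] = adj[b, a] = True
        return PatientGraph("p", [f"t{i}" for i in range(n)], X,
                            np.full(n, 1 / n), E, adj)

    def test_single_node_self_loop(self, rng):
        g = self._graph(rng, n=1, edges=())
        params = GraphAttentionParams.init(5, 1, 4, rng)
        out, alpha = gatv2_layer(g, params)
        assert alpha[0, 0, 0] == pytest.approx(1.0)
        Xp = g.node_features @ params.W[0].T
        msg = np.hstack([Xp, np.ones((1, 1))]) @ params.M[0].T
        res = g.node_features @ params.residual.T
        np.testing.assert_allclose(out, msg + res)

    def test_symmetric_neighbors_share_attention(self, rng):
        X = np.zeros((3, 4))
        X[1] = X[2] = 1.0  # identical neighbor features
        E = np.eye(3)
        E[0, 1] = E[1, 0] = E[0, 2] = E[2, 0] = 0.5
        adj = E != 0
        g = PatientGraph("p", ["a", "b", "c"], X, np.full(3, 1 / 3), E, adj)
        params = GraphAttentionParams.init(4, 2, 3, rng)
        _, alpha = gatv2_layer(g, params)
        np.testing.assert_allclose(alpha[:, 0, 1], alpha[:, 0, 2],
                                   atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        g = self._graph(rng)
        _, alpha = gatv2_layer(g, GraphAttentionParams.init(5, 2, 4, rng))
        np.testing.assert_allclose(alpha.sum(axis=2), 1.0, atol=1e-9)

    @pytest.mark.parametrize("variant", ["as_printed", "v2"])
    def test_three_node_loop_oracle(self, rng, variant):
        """H=2, D=4 layer equals an index-wise scalar evaluation."""
        g = self._graph(rng)
        params = GraphAttentionParams.init(5, 2, 4, rng, variant=variant)
        out, alpha = gatv2_layer(g, params)

        def leaky(v):
            return np.where(v > 0, v, 0.2 * v)

        outs = []
        for h in range(2):
            Xp = g.node_features @ params.W[h].T
            a1, a2, ae = (params.att[h, :4], params.att[h, 4:8],
                          params.att[h, 8])
            n = 3
            S = np.full((n, n), -np.inf)
            for i in range(n):
                for j in range(n):
                    if not g.adjacency[i, j]:
                        continue
                    if variant == "as_printed":
                        S[i, j] = leaky(a1 @ Xp[i] + a2 @ Xp[j]
                                        + ae * g.edge_features[i, j])
                    else:
                        S[i, j] = (a1 @ leaky(Xp[i]) + a2 @ leaky(Xp[j])
                                   + ae * leaky(g.edge_features[i, j]))
            A = np.zeros((n, n))
            for i in range(n):
                e = np.exp(S[i][g.adjacency[i]] - S[i][g.adjacency[i]].max())
                A[i, g.adjacency[i]] = e / e.sum()
            m = np.zeros((n, 4))
            for i in range(n):
                agg = np.zeros(5)
                for j in range(n):
                    agg += A[i, j] * np.append(Xp[j], g.edge_features[i, j])
                m[i] = params.M[h] @ agg
            outs.append(m)
            np.testing.assert_allclose(alpha[h], A, atol=1e-12)
        expected = np.hstack(outs) + g.node_features @ params.residual.T
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        g = self._graph(rng)
        params = GraphAttentionParams.init(5, 2, 4, rng)
        out, _ = gatv2_layer(g, params)
        perm = [2, 0, 1]
        gp = PatientGraph("p", [g.node_names[i] for i in perm],
                          g.node_features[perm], g.proportions[perm],
                          g.edge_features[np.ix_(perm, perm)],
                          g.adjacency[np.ix_(perm, perm)])
        out_p, _ = gatv2_layer(gp, params)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)
        np.testing.assert_allclose(
            graph_readout(out_p, gp.proportions),
            graph_readout(out, g.proportions), atol=1e-10)

    def test_edge_removal_only_affects_incident_nodes(self, rng):
        g = self._graph(rng, n=4, edges=((0, 1), (2, 3)))
        params = GraphAttentionParams.init(5, 1, 4, rng)
        _, alpha_before = gatv2_layer(g, params)
        g2 = PatientGraph("p", g.node_names, g.node_features, g.proportions,
                          g.edge_features.copy(), g.adjacency.copy())
        g2.edge_features[2, 3] = g2.edge_features[3, 2] = 0.0
        g2.adjacency[2, 3] = g2.adjacency[3, 2] = False
        _, alpha_after = gatv2_layer(g2, params)
        np.testing.assert_allclose(alpha_after[:, :2], alpha_before[:, :2],
                                   atol=1e-12)

    def test_node_without_self_loop_rejected(self, rng):
        adj = np.eye(3, dtype=bool)
        adj[0, 0] = False  # node with no neighbors and no self-loop
        with pytest.raises(ValidationError):
            PatientGraph("p", ["a", "b", "c"], rng.standard_normal((3, 4)),
                         np.full(3, 1 / 3), np.eye(3), adj)


class TestReadout:
    def test_single_type_returns_its_feature(self, rng):
        x = rng.standard_normal((1, 4))
        np.testing.assert_array_equal(graph_readout(x, np.array([1.0])),
                                      x[0])

    def test_identical_features_ignore_proportions(self, rng):
        x = np.tile(rng.standard_normal(4), (3, 1))
        out = graph_readout(x, np.array([0.7, 0.2, 0.1]))
        np.testing.assert_allclose(out, x[0])

    def test_weighted_mean_oracle(self, rng):
        x = rng.standard_normal((3, 4))
        w = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(graph_readout(x, w),
                                   (w[:, None] * x).sum(axis=0))

    def test_zero_proportions_error(self, rng):
        with pytest.raises(ValidationError):
            graph_readout(rng.standard_normal((2, 3)), np.zeros(2))


def test_pseudobulk_matrix_pools_columns(small_sc_prep):
    pooled = pseudobulk_matrix(small_sc_prep.profiles)
    total = sum(len(p.cell_types) for p in small_sc_prep.profiles.values())
    assert pooled.n_samples == total
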