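"""Pearson co-expression edges, degrees, RMS fold-change scores and the
composite hub rule."""

import numpy as np
import pandas as pd
import pytest

import floranet as fn
from floranet.netcore import Edge, NetworkError, _top_k_cutoff, pearson_pvalue


def feature_matrix(profiles: dict[str, list[float]], kinds=None) -> fn.FeatureMatrix:
    frame = pd.DataFrame(profiles).T
    frame = frame.sub(frame.mean(axis=1), axis=0).div(frame.std(axis=1, ddof=0), axis=0)
    kinds = kinds or {k: "gene" for k in profiles}
    return fn.FeatureMatrix(profiles=frame, kinds=pd.Series(kinds))


class TestAssembleCandidates:
    def test_kinds_resolved(self, small_fpkm, small_config, small_dataset):
        _, truth = small_dataset
        compounds = fn.simulate_compounds(small_config, truth)
        genes = list(small_fpkm.gene_ids[:2])
        feats = fn.assemble_candidates(small_fpkm, compounds, genes + ["ZT"])
        assert list(feats.kinds) == ["gene", "gene", "hormone"]
        assert feats.profiles.shape == (3, 24)
        # z-standardized
        assert np.allclose(feats.profiles.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(feats.profiles.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_unresolvable_candidate(self, small_fpkm):
        with pytest.raises(NetworkError, match="nosuchthing"):
            fn.assemble_candidates(small_fpkm, None, ["nosuchthing"])

    def test_constant_profile_excluded_with_warning(self, small_fpkm):
        fpkm = fn.FpkmMatrix(fpkm=small_fpkm.fpkm.copy(), lengths=small_fpkm.lengths)
        fpkm.fpkm.iloc[0, :] = 3.0
        flat = fpkm.gene_ids[0]
        keep = fpkm.gene_ids[1]
        with pytest.warns(UserWarning, match="constant"):
            feats = fn.assemble_candidates(fpkm, None, [flat, keep])
        assert list(feats.feature_ids) == [keep]
        assert feats.excluded_constant == [flat]

    def test_z_standardization_preserves_pearson(self, small_fpkm):
        genes = list(small_fpkm.gene_ids[:6])
        feats = fn.assemble_candidates(small_fpkm, None, genes, log_scale=False)
        raw = small_fpkm.fpkm.loc[genes].to_numpy()
        assert np.allclose(np.corrcoef(feats.profiles.to_numpy()), np.corrcoef(raw))


class TestPearsonEdges:
    def test_perfect_linearity(self):
        feats = feature_matrix({"x": [1, 2, 3], "y": [2, 4, 6]})
        edges = fn.pearson_edges(feats, fn.NetParams(alpha_edge=1.0))
        assert len(edges) == 1 and edges[0].r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # cov = 0.5, sd_x = sd_y = 1 over (1,2,3) vs (1,3,2) -> r = 0.5
        x, y = np.array([1, 2, 3.0]), np.array([1, 3, 2.0])
        r = np.mean((x - 2) * (y - 2)) / (x.std() * y.std())
        assert r == pytest.approx(0.5)
        feats = feature_matrix({"x": list(x), "y": list(y)})
        assert np.corrcoef(feats.profiles.to_numpy())[0, 1] == pytest.approx(0.5)

    def test_r_one_p_zero_no_blowup(self):
        p = pearson_pvalue(np.array([1.0, -1.0]), 3)
        assert (p == 0.0).all()
        assert p[0] < 1e-12

    def test_fewer_than_three_samples_rejected(self):
        frame = pd.DataFrame({"x": [1.0, -1.0], "y": [1.0, -1.0]}).T
        feats = fn.FeatureMatrix(profiles=frame, kinds=pd.Series({"x": "gene", "y": "gene"}))
        with pytest.raises(NetworkError, match="samples"):
            fn.pearson_edges(feats, fn.NetParams())

    def test_threshold_filters(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        feats = feature_matrix(
            {"a": list(x), "b": list(x + rng.normal(scale=0.1, size=24)),
             "c": list(rng.normal(size=24))}
        )
        edges = fn.pearson_edges(feats, fn.NetParams(r_min=0.8, alpha_edge=0.05))
        assert {(e.u, e.v) for e in edges} == {("a", "b")}


class TestDegrees:
    def test_path_graph(self):
        edges = [Edge("a", "b", 0.9, 0.001), Edge("b", "c", 0.9, 0.001)]
        deg = fn.node_degree(edges, ["a", "b", "c"])
        assert deg.to_dict() == {"a": 1, "b": 2, "c": 1}

    def test_empty_edges_all_zero(self):
        assert fn.node_degree([], ["a", "b"]).to_dict() == {"a": 0, "b": 0}

    def test_handshake_identity_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(20)]
            pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
            chosen = [pairs[i] for i in rng.choice(len(pairs), size=30, replace=False)]
            edges = [Edge(u, v, 0.9, 0.01) for u, v in chosen]
            deg = fn.node_degree(edges, nodes)
            assert deg.sum() == 2 * len(edges)


class TestRmsLfc:
    @pytest.mark.parametrize(
        "a,b,expected", [(0, 0, 0.0), (2.5, 2.5, 2.5), (-1.7, 1.7, 1.7),
                         (3, 4, np.sqrt(12.5))]
    )
    def test_values(self, a, b, expected):
        assert fn.rms_lfc(a, b) == pytest.approx(expected)


class TestSelectHubs:
    def toy(self):
        """5 nodes; degrees (3,3,2,1,1); s = (2, 0.1, 2, 2, 2)."""
        edges = [
            Edge("n1", "n2", 0.9, 1e-4), Edge("n1", "n3", 0.9, 1e-4),
            Edge("n1", "n4", 0.9, 1e-4), Edge("n2", "n3", 0.9, 1e-4),
            Edge("n2", "n5", 0.9, 1e-4),
        ]
        profiles = {f"n{i}": list(np.random.default_rng(i).normal(size=6)) for i in range(1, 6)}
        feats = feature_matrix(profiles)
        scores = pd.Series({"n1": 2.0, "n2": 0.1, "n3": 2.0, "n4": 2.0, "n5": 2.0})
        return feats, edges, scores

    def test_toy_quantile_example(self):
        feats, edges, scores = self.toy()
        table = fn.select_hubs(feats, edges, scores, fn.NetParams())
        hubs = set(table.loc[table["is_hub"], "feature"])
        assert hubs == {"n1"}  # only node with top-40% degree AND top-40% s

    def test_empty_network_no_hubs(self):
        feats, _, scores = self.toy()
        with pytest.warns(UserWarning, match="no edges"):
            table = fn.select_hubs(feats, [], scores, fn.NetParams())
        assert not table["is_hub"].any()

    def test_raising_score_quantile_shrinks_hub_set(self):
        feats, edges, scores = self.toy()
        previous = None
        for q in (0.2, 0.4, 0.6, 0.8):
            table = fn.select_hubs(feats, edges, scores,
                                   fn.NetParams(score_quantile=q))
            hubs = set(table.loc[table["is_hub"], "feature"])
            if previous is not None:
                assert hubs <= previous
            previous = hubs

    def test_input_order_invariance(self):
        feats, edges, scores = self.toy()
        reordered = fn.FeatureMatrix(
            profiles=feats.profiles.iloc[::-1], kinds=feats.kinds.iloc[::-1]
        )
        t1 = fn.select_hubs(feats, edges, scores, fn.NetParams())
        t2 = fn.select_hubs(reordered, edges, scores, fn.NetParams())
        h1 = set(t1.loc[t1["is_hub"], "feature"])
        h2 = set(t2.loc[t2["is_hub"], "feature"])
        assert h1 == h2

    def test_affine_rescaling_invariance(self, small_fpkm, scheme):
        """Rescaling a feature's raw profile does not change the hub set."""
        genes = list(small_fpkm.gene_ids[:12])
        feats = fn.assemble_candidates(small_fpkm, None, genes, log_scale=False)
        scaled_fpkm = fn.FpkmMatrix(fpkm=small_fpkm.fpkm.copy(), lengths=small_fpkm.lengths)
        scaled_fpkm.fpkm.loc[genes[0]] = scaled_fpkm.fpkm.loc[genes[0]] * 7.0 + 3.0
        feats2 = fn.assemble_candidates(scaled_fpkm, None, genes, log_scale=False)
        params = fn.NetParams(r_min=0.5, alpha_edge=0.5)
        lfc1 = fn.log2_fold_change(small_fpkm, scheme["M3vsF3"])
        lfc2 = fn.log2_fold_change(small_fpkm, scheme["M4vsF4"])
        scores = pd.Series({g: fn.rms_lfc(lfc1[g], lfc2[g]) for g in genes})
        t1 = fn.select_hubs(feats, fn.pearson_edges(feats, params), scores, params)
        t2 = fn.select_hubs(feats2, fn.pearson_edges(feats2, params), scores, params)
        assert set(t1.loc[t1["is_hub"], "feature"]) == set(t2.loc[t2["is_hub"], "feature"])


def test_top_k_cutoff_nearest_rank():
    values = np.array([3.0, 1.0, 2.0, 3.0, 1.0])
    assert _top_k_cutoff(values, 0.4) == 3.0   # top 40% of 5 -> 2nd largest
    assert _top_k_cutoff(values, 0.9) == 1.0
    assert _top_k_cutoff(values, 0.01) == 3.0  # k floors at 1


def test_edge_canonical_order():
    e = Edge("z", "a", 0.9, 0.01)
    assert (e.u, e.v) == ("a", "z")
    with pytest.raises(NetworkError):
        Edge("a", "a", 1.0, 0.0)
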