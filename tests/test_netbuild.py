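import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncgo.netbuild import (ComponentNetwork, EntityIndex, ExpressionMatrix,
                            FusionConfig, assemble_global,
                            binarize_interactions, fuse_scores, merge_max,
                            pcc_similarity)

from conftest import empty_components


class TestEntityIndex:
    def test_block_order_and_offsets(self):
        idx = EntityIndex(["l1", "l2"], ["p1"], ["m1", "m2"])
        assert idx.ids() == ["l1", "l2", "p1", "m1", "m2"]
        assert idx.global_index("p1") == 2
        assert idx.global_index("m2") == 4
        assert idx.offsets == {"lncrna": 0, "protein": 2, "mirna": 3}

    def test_duplicate_ids_across_kinds_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            EntityIndex(["x"], ["x"], [])


class TestPccSimilarity:
    def test_identical_profiles_have_similarity_one(self):
        expr = ExpressionMatrix(("a", "b"), ("s1", "s2", "s3"),
                                [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        net = pcc_similarity(expr)
        assert net.get("a", "b") == pytest.approx(1.0)

    def test_perfect_anticorrelation_clipped_to_absent(self):
        expr = ExpressionMatrix(("a", "b"), ("s1", "s2", "s3"),
                                [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        net = pcc_similarity(expr, clip_negative=True)
        assert net.n_edges() == 0

    def test_matches_per_pair_pcc_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.random((5, 8))
        ids = tuple(f"e{i}" for i in range(5))
        expr = ExpressionMatrix(ids, tuple(f"s{j}" for j in range(8)), vals)
        net = pcc_similarity(expr, clip_negative=False)
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = vals[i] - vals[i].mean(), vals[j] - vals[j].mean()
                r = float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))
                assert net.get(ids[i], ids[j]) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_row_names_entity(self):
        expr = ExpressionMatrix(("ok", "flat"), ("s1", "s2"),
                                [[1.0, 2.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="flat"):
            pcc_similarity(expr)

    def test_single_sample_rejected(self):
        expr = ExpressionMatrix(("a", "b"), ("s1",), [[1.0], [2.0]])
        with pytest.raises(ValueError, match="sample"):
            pcc_similarity(expr)

    @given(slope=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_positive_affine_transform(self, slope, shift):
        rng = np.random.default_rng(5)
        vals = rng.random((4, 6))
        ids = ("a", "b", "c", "d")
        samples = tuple(f"s{j}" for j in range(6))
        base = pcc_similarity(ExpressionMatrix(ids, samples, vals))
        scaled = vals.copy()
        scaled[0] = slope * scaled[0] + shift
        trans = pcc_similarity(ExpressionMatrix(ids, samples, scaled))
        for a, b, w in base.edges():
            assert trans.get(a, b) == pytest.approx(w, abs=1e-9)


class TestFuseScores:
    def test_single_source_is_identity(self):
        fused = fuse_scores(FusionConfig([{("l", "p"): 0.8}]))
        assert fused[("l", "p")] == pytest.approx(0.8)

    def test_two_halves_fuse_to_three_quarters(self):
        fused = fuse_scores(FusionConfig([{("l", "p"): 0.5}, {("l", "p"): 0.5}]))
        assert fused[("l", "p")] == pytest.approx(0.75)

    def test_negative_scores_dropped_before_fusion(self):
        fused = fuse_scores(FusionConfig([{("l", "p"): 0.6}, {("l", "p"): -0.3},
                                          {("l", "p"): 0.2}]))
        assert fused[("l", "p")] == pytest.approx(1 - 0.4 * 0.8)

    def test_pair_with_no_positive_score_absent(self):
        fused = fuse_scores(FusionConfig([{("l", "p"): -0.6}]))
        assert ("l", "p") not in fused

    def test_score_above_one_rejected(self):
        with pytest.raises(ValueError, match="probability-like"):
            fuse_scores(FusionConfig([{("l", "p"): 1.2}]))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
           st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_dominates_max_source(self, scores, extra):
        base = fuse_scores(FusionConfig([{("l", "p"): s} for s in scores]))
        more = fuse_scores(FusionConfig([{("l", "p"): s}
                                         for s in scores + [extra]]))
        assert more[("l", "p")] >= base[("l", "p")] - 1e-12
        assert base[("l", "p")] >= max(scores) - 1e-12
        assert 0 < base[("l", "p")] <= 1


class TestBinarize:
    def test_listed_pairs_get_weight_one(self, small_index):
        net = binarize_interactions([("l1", "p1"), ("l1", "p2"), ("l2", "p1")],
                                    small_index, "lncrna", "protein")
        assert net.n_edges() == 3
        assert all(w == 1.0 for _, _, w in net.edges())

    def test_empty_pair_list(self, small_index):
        net = binarize_interactions([], small_index, "lncrna", "protein")
        assert net.n_edges() == 0

    def test_duplicate_pair_collapses(self, small_index):
        net = binarize_interactions([("l1", "p1"), ("l1", "p1")],
                                    small_index, "lncrna", "protein")
        assert net.n_edges() == 1

    def test_unknown_ids_listed_in_error(self, small_index):
        with pytest.raises(ValueError, match="ghost"):
            binarize_interactions([("l1", "ghost")], small_index,
                                  "lncrna", "protein")


class TestComponentNetwork:
    def test_conflicting_duplicate_weight_rejected(self):
        net = ComponentNetwork("lncrna", "lncrna")
        net.add_edge("a", "b", 0.5)
        net.add_edge("b", "a", 0.5)  # symmetric duplicate, agreeing
        with pytest.raises(ValueError, match="conflicting"):
            net.add_edge("a", "b", 0.6)

    def test_merge_max_keeps_larger_evidence(self):
        a = ComponentNetwork("lncrna", "protein")
        a.add_edge("l", "p", 0.4)
        b = ComponentNetwork("lncrna", "protein")
        b.add_edge("l", "p", 1.0)
        b.add_edge("l", "q", 0.3)
        merged = merge_max(a, b)
        assert merged.get("l", "p") == 1.0
        assert merged.get("l", "q") == 0.3


class TestAssembleGlobal:
    def test_all_empty_gives_zero_matrix(self, small_index):
        G = assemble_global(index=small_index, **empty_components())
        assert G.matrix.shape == (5, 5)
        assert G.matrix.nnz == 0

    def test_hand_placed_cross_edge(self, small_index):
        nets = empty_components()
        nets["LP"].add_edge("l1", "p2", 0.5)
        G = assemble_global(index=small_index, **nets)
        dense = G.toarray()
        assert dense[0, 3] == 0.5 and dense[3, 0] == 0.5
        assert np.count_nonzero(dense) == 2

    def test_symmetry_and_nonnegativity_on_random_input(self):
        rng = np.random.default_rng(0)
        idx = EntityIndex([f"l{i}" for i in range(4)],
                          [f"p{i}" for i in range(5)],
                          [f"m{i}" for i in range(3)])
        nets = empty_components()
        specs = {"L": ("l", 4, "l", 4), "P": ("p", 5, "p", 5),
                 "M": ("m", 3, "m", 3), "LP": ("l", 4, "p", 5),
                 "LM": ("l", 4, "m", 3), "PM": ("p", 5, "m", 3)}
        for key, (pa, na, pb, nb) in specs.items():
            for i in range(na):
                for j in range(nb):
                    if pa == pb and j <= i:
                        continue
                    if rng.random() < 0.5:
                        nets[key].add_edge(f"{pa}{i}", f"{pb}{j}", rng.random())
        G = assemble_global(index=idx, **nets)
        dense = G.toarray()
        assert np.abs(dense - dense.T).max() == 0.0
        assert dense.min() >= 0
        # block extraction recovers each component bit-exactly
        for key, (pa, na, pb, nb) in specs.items():
            kinds = {"l": "lncrna", "p": "protein", "m": "mirna"}
            block = G.block(kinds[pa], kinds[pb]).toarray()
            for i in range(na):
                for j in range(nb):
                    assert block[i, j] == nets[key].get(f"{pa}{i}", f"{pb}{j}")

    def test_wrong_kind_component_rejected(self, small_index):
        nets = empty_components()
        nets["LP"] = ComponentNetwork("lncrna", "mirna")
        with pytest.raises(ValueError, match="kinds"):
            assemble_global(index=small_index, **nets)

    def test_unknown_endpoint_rejected(self, small_index):
        nets = empty_components()
        nets["LP"].add_edge("l1", "p9", 0.5)
        with pytest.raises(ValueError, match="p9"):
            assemble_global(index=small_index, **nets)

    def test_drop_kind_removes_exactly_that_block(self, small_index):
        nets = empty_components()
        nets["LP"].add_edge("l1", "p1", 0.3)
        nets["LM"].add_edge("l2", "m1", 0.7)
        G = assemble_global(index=small_index, **nets)
        G2 = G.drop_kind("mirna")
        assert G2.index.n_total == 4
        assert (G2.matrix.toarray() == G.matrix.toarray()[:4, :4]).all()
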