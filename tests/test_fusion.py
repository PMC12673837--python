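"""Masked attention semantics, hierarchical fusion invariances, flat fusion
equivalence, alignment diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtifuse.autodiff import Tensor
from dtifuse.datamodel import ValidationError
from dtifuse.fusion import (
    AttentionRecord,
    ClusterLayout,
    FlatFusion,
    HierarchicalFusion,
    alignment_score,
    check_alignment_margin,
    flat_softmax_fusion,
    masked_intra_cluster_attention,
)


class TestMaskedAttention:
    def test_identical_embeddings_share_weight(self):
        z = np.tile([1.0, 2.0], (2, 1))
        _, rec = masked_intra_cluster_attention(z, [1, 1], np.ones(2))
        assert np.allclose(rec.weights, [0.5, 0.5])

    def test_single_survivor_takes_all(self):
        z = np.array([[1.0, 0.0], [5.0, 5.0]])
        u, rec = masked_intra_cluster_attention(z, [1, 0], np.ones(2))
        assert np.allclose(rec.weights, [1.0, 0.0])
        assert np.allclose(u, z[0])

    def test_hand_evaluated_softmax(self):
        # logits (ln 2, 0) -> weights (2/3, 1/3)
        z = np.array([[np.log(2.0)], [0.0]])
        u, rec = masked_intra_cluster_attention(z, [1, 1], np.array([1.0]))
        assert np.allclose(rec.weights, [2 / 3, 1 / 3], atol=1e-12)
        assert np.allclose(u, 2 / 3 * np.log(2.0))

    def test_all_masked_is_contract_violation(self):
        with pytest.raises(ValidationError):
            masked_intra_cluster_attention(np.ones((2, 2)), [0, 0], np.ones(2))

    def test_masked_weights_equal_subset_softmax(self, rng):
        """Oracle: masked formula == plain softmax on the present subset."""
        K, d = 4, 6
        for pattern in itertools.product([0, 1], repeat=K):
            if not any(pattern):
                continue
            z = rng.standard_normal((K, d))
            q = rng.standard_normal(d)
            _, rec = masked_intra_cluster_attention(z, pattern, q)
            idx = [k for k in range(K) if pattern[k]]
            logits = z[idx] @ q
            expected = np.exp(logits - logits.max())
            expected /= expected.sum()
            assert np.allclose(rec.weights[idx], expected, atol=1e-9)
            assert (rec.weights[[k for k in range(K) if not pattern[k]]] == 0).all()

    def test_dropping_zero_weight_modality_keeps_fused_vector(self, rng):
        z = rng.standard_normal((3, 4))
        q = rng.standard_normal(4)
        u_full, rec = masked_intra_cluster_attention(z, [1, 1, 0], q)
        u_sub, _ = masked_intra_cluster_attention(z[:2], [1, 1], q)
        assert (u_full == u_sub).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 15))
    def test_weight_invariants_hold_for_random_inputs(self, seed, pat):
        rng = np.random.default_rng(seed)
        delta = np.array([(pat >> k) & 1 for k in range(4)])
        z = rng.standard_normal((4, 5)) * 10
        _, rec = masked_intra_cluster_attention(z, delta, rng.standard_normal(5))
        rec.check(delta)  # non-negative, masked zero, sums to one


class TestFlatFusion:
    def test_convexity_fixed_point(self):
        z = np.tile([0.3, -0.7], (3, 1))
        fused, _ = flat_softmax_fusion(z, [1, 1, 1], np.ones(2))
        assert np.allclose(fused, z[0])

    def test_single_modality_identity(self):
        z = np.array([[2.0, 1.0]])
        fused, rec = flat_softmax_fusion(z, [1], np.ones(2))
        assert np.allclose(fused, z[0]) and rec.level == "flat"

    def test_matches_intra_cluster_with_one_cluster(self, rng):
        z = rng.standard_normal((4, 3))
        w = rng.standard_normal(3)
        delta = np.array([1, 0, 1, 1])
        f1, r1 = flat_softmax_fusion(z, delta, w)
        f2, r2 = masked_intra_cluster_attention(z, delta, w)
        assert np.allclose(r1.weights, r2.weights, atol=1e-12)
        assert np.allclose(f1, f2)


class TestAlignmentScore:
    def test_self_alignment_is_one(self, rng):
        v = rng.standard_normal(8)
        assert alignment_score(v, v) == pytest.approx(1.0)

    def test_antipodal_is_minus_one(self, rng):
        v = rng.standard_normal(8)
        assert alignment_score(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_is_zero(self):
        assert alignment_score([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            alignment_score([0.0, 0.0], [1.0, 0.0])

    def test_margin_check_identical_embeddings(self):
        batch = {"graph": np.ones((3, 4)), "protein_seq": np.ones((3, 4))}
        out = check_alignment_margin(batch, "graph", margin=0.99)
        assert out["protein_seq"]["mean_alignment"] == pytest.approx(1.0)
        assert out["protein_seq"]["passes"]

    def test_margin_check_reference_only_batch_is_empty(self):
        assert check_alignment_margin({"graph": np.ones((2, 3))}, "graph", 0.5) == {}

    def test_random_high_dim_cosines_concentrate_near_zero(self, rng):
        d, n = 512, 200
        batch = {"a": rng.standard_normal((n, d)), "b": rng.standard_normal((n, d))}
        out = check_alignment_margin(batch, "a", margin=0.5)
        assert abs(out["b"]["mean_alignment"]) < 0.02
        assert not out["b"]["passes"]


class TestClusterLayout:
    def test_default_grouping_covers_all(self):
        names = ["graph", "smiles", "protein_seq", "bioassay"]
        layout = ClusterLayout.default(names)
        layout.validate_covers(names)
        assert layout.clusters["chemical"] == ["graph", "smiles"]

    def test_disjointness_enforced(self):
        with pytest.raises(ValidationError):
            ClusterLayout({"a": ["graph"], "b": ["graph"]})

    def test_incomplete_layout_rejected(self):
        layout = ClusterLayout({"a": ["graph"]})
        with pytest.raises(ValidationError):
            layout.validate_covers(["graph", "smiles"])


def _projected(rng, names, B, d):
    return {m: Tensor(rng.standard_normal((B, d))) for m in names}


class TestHierarchicalFusion:
    names = ["graph", "smiles", "protein_seq"]

    def _fusion(self, clusters, d=8, seed=0):
        return HierarchicalFusion(self.names, d,
                                  ClusterLayout(clusters),
                                  np.random.default_rng(seed))

    def test_cluster_order_invariance(self, rng):
        d, B = 8, 3
        proj = _projected(rng, self.names, B, d)
        delta = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 1]])
        base = {"c1": ["graph"], "c2": ["smiles"], "c3": ["protein_seq"]}
        outs = []
        for order in itertools.permutations(base):
            f = self._fusion({k: base[k] for k in order}, d=d, seed=3)
            z, _ = f(proj, delta)
            outs.append(z.data)
        for o in outs[1:]:
            assert np.allclose(o, outs[0], atol=1e-8)

    def test_single_cluster_is_deterministic_function_of_u(self, rng):
        d = 8
        proj = _projected(rng, self.names, 2, d)
        f = self._fusion({"all": self.names}, d=d)
        z1, _ = f(proj, np.ones((2, 3), int))
        z2, _ = f(proj, np.ones((2, 3), int))
        assert (z1.data == z2.data).all()
        assert z1.shape == (2, d)

    def test_empty_cluster_is_skipped_not_zero_filled(self, rng):
        d = 8
        proj = _projected(rng, self.names, 2, d)
        f = self._fusion({"c1": ["graph", "smiles"], "c2": ["protein_seq"]}, d=d)
        # protein_seq missing everywhere: output must match a layout that
        # never declared that cluster's inputs as present
        delta = np.array([[1, 1, 0], [1, 1, 0]])
        z, trace = f(proj, delta, collect_trace=True)
        assert z.shape == (2, d)
        intra = [t for t in trace if t.level == "intra_cluster"
                 and t.participants == ["protein_seq"]]
        assert all(np.allclose(t.weights, 0.0) for t in intra)

    def test_trace_records_satisfy_invariants(self, rng):
        proj = _projected(rng, self.names, 4, 8)
        delta = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 1], [1, 1, 0]])
        f = self._fusion({"c1": ["graph", "smiles"], "c2": ["protein_seq"]})
        _, trace = f(proj, delta, collect_trace=True)
        name_cols = {n: i for i, n in enumerate(self.names)}
        for b, rec in enumerate([t for t in trace if t.participants == ["graph", "smiles"]]):
            sub = delta[b, [name_cols[p] for p in rec.participants]]
            if sub.any():
                rec.check(sub)

    def test_reweight_zero_excludes_modality(self, rng):
        d = 8
        proj = _projected(rng, self.names, 2, d)
        f = self._fusion({"all": self.names}, d=d)
        rw = Tensor(np.array([[1.0, 0.0, 1.0], [1.0, 0.0, 1.0]]))
        z_rw, _ = f(proj, np.ones((2, 3), int), reweight=rw)
        z_drop, _ = f(proj, np.array([[1, 0, 1], [1, 0, 1]]))
        assert np.allclose(z_rw.data, z_drop.data, atol=1e-9)


class TestFlatFusionModule:
    def test_flat_module_matches_reference_op(self, rng):
        names = ["a_mod", "b_mod", "c_mod"]
        # module accepts arbitrary names
        d = 6
        f = FlatFusion(names, d, np.random.default_rng(1))
        proj = _projected(rng, names, 1, d)
        delta = np.array([[1, 1, 0]])
        z, trace = f(proj, delta, collect_trace=True)
        stackz = np.stack([proj[m].data[0] for m in names])
        ref, rec = flat_softmax_fusion(stackz, delta[0], f.w.data)
        assert np.allclose(trace[0].weights, rec.weights, atol=1e-12)
        assert np.allclose(z.data[0], ref, atol=1e-12)
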