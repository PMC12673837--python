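"""Encoder contracts: permutation invariance, pad invariance, readout
additivity, projection typing, stochastic-mode behaviour."""

import itertools

import numpy as np
import pytest

from dtifuse.autodiff import Tensor
from dtifuse.datamodel import MolecularGraph, ValidationError, Vocab
from dtifuse.encoders import (
    EncoderConfig,
    GraphEncoder,
    MultimodalEncoder,
    PassthroughEncoder,
    SequenceEncoder,
    TabularEncoder,
    build_graph_batch,
    build_token_batch,
    infer_schema,
)


def small_cfg(**kw):
    base = dict(unified_dim=16, graph_hidden=8, seq_d_model=8, seq_layers=1,
                attention_heads=2, tabular_latent=8, dropout_rate=0.3,
                seq_max_len=32)
    base.update(kw)
    return EncoderConfig(**base)


def relabeled_path(order):
    """Path a-b-c with node features tied to the *logical* node, stored in
    permuted positions."""
    base_feats = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    pos = {logical: slot for slot, logical in enumerate(order)}
    feats = np.zeros((3, 3))
    for logical in range(3):
        feats[pos[logical]] = base_feats[logical]
    edges = np.array([[pos[0], pos[1]], [pos[1], pos[2]]])
    return MolecularGraph(feats, edges, np.ones((2, 1)))


class TestGraphEncoder:
    def test_permutation_invariance_all_orderings(self):
        rng = np.random.default_rng(0)
        enc = GraphEncoder(d_v=3, d_e=1, cfg=small_cfg(), rng=rng)
        outs = []
        for order in itertools.permutations(range(3)):
            g = relabeled_path(order)
            outs.append(enc(build_graph_batch([g])).data)
        for o in outs[1:]:
            assert np.allclose(o, outs[0], atol=1e-10)

    def test_sum_readout_additive_under_disjoint_union(self):
        rng = np.random.default_rng(1)
        enc = GraphEncoder(d_v=2, d_e=1, cfg=small_cfg(readout="sum"), rng=rng)
        g = MolecularGraph(np.array([[1.0, 0.5], [0.2, 0.3]]),
                           np.array([[0, 1]]), np.ones((1, 1)))
        single = enc(build_graph_batch([g])).data
        union = MolecularGraph(
            np.vstack([g.node_features, g.node_features]),
            np.array([[0, 1], [2, 3]]), np.ones((2, 1)))
        doubled = enc(build_graph_batch([union])).data
        assert np.allclose(doubled, 2 * single, atol=1e-10)

    def test_isolated_node_uses_zero_message_sum(self):
        rng = np.random.default_rng(2)
        cfg = small_cfg(readout="mean", dropout_rate=0.0)
        enc = GraphEncoder(d_v=2, d_e=1, cfg=cfg, rng=rng)
        g = MolecularGraph(np.array([[0.7, -0.2]]), np.zeros((0, 2)), np.zeros((0, 1)))
        out = enc(build_graph_batch([g])).data[0]
        # manual: h = in_proj(x); then per layer h = relu(W h + 0)
        h = g.node_features @ enc.in_proj.W.data + enc.in_proj.b.data
        for w in enc.self_layers:
            h = np.maximum(h @ w.W.data + w.b.data, 0.0)
        assert np.allclose(out, h[0], atol=1e-12)

    @pytest.mark.parametrize("readout", ["mean", "sum", "attention"])
    def test_readouts_are_deterministic_without_rng(self, readout):
        rng = np.random.default_rng(3)
        enc = GraphEncoder(d_v=3, d_e=1, cfg=small_cfg(readout=readout), rng=rng)
        g = relabeled_path((0, 1, 2))
        a = enc(build_graph_batch([g])).data
        b = enc(build_graph_batch([g])).data
        assert (a == b).all()


class TestSequenceEncoder:
    def test_pad_length_does_not_change_output(self):
        rng = np.random.default_rng(4)
        enc = SequenceEncoder(vocab_size=10, cfg=small_cfg(dropout_rate=0.0), rng=rng)
        short = np.array([[1, 4, 5, 0]])
        long = np.array([[1, 4, 5, 0, 0, 0, 0]])
        assert np.allclose(enc(short).data, enc(long).data, atol=1e-10)

    def test_output_dim_independent_of_length(self):
        rng = np.random.default_rng(5)
        enc = SequenceEncoder(vocab_size=10, cfg=small_cfg(), rng=rng)
        for L in (3, 9, 17):
            ids = np.concatenate([[1], np.full(L, 4)])[None, :]
            assert enc(ids).shape == (1, 8)

    def test_all_pad_sequence_rejected(self):
        rng = np.random.default_rng(6)
        enc = SequenceEncoder(vocab_size=10, cfg=small_cfg(), rng=rng)
        with pytest.raises(ValidationError):
            enc(np.zeros((1, 4), dtype=np.int64))

    def test_max_pool_operator_is_monotone_in_added_positions(self):
        rng = np.random.default_rng(7)
        hidden = rng.standard_normal((2, 5, 4))
        mask = np.ones((2, 5), bool)
        pooled = SequenceEncoder.max_pool(hidden, mask)
        extended = np.concatenate([hidden, rng.standard_normal((2, 1, 4))], axis=1)
        mask_ext = np.ones((2, 6), bool)
        pooled_ext = SequenceEncoder.max_pool(extended, mask_ext)
        assert (pooled_ext >= pooled - 1e-12).all()

    def test_cls_concat_mode_doubles_latent(self):
        rng = np.random.default_rng(8)
        enc = SequenceEncoder(vocab_size=10, cfg=small_cfg(cls_combine="concat"), rng=rng)
        assert enc.latent_dim == 16
        assert enc(np.array([[1, 3, 4]])).shape == (1, 16)


class TestTabularEncoder:
    def test_identity_weights_pass_nonnegative_input(self):
        rng = np.random.default_rng(9)
        enc = TabularEncoder(4, small_cfg(tabular_latent=4, dropout_rate=0.0), rng)
        enc.lin.W.data = np.eye(4)
        enc.lin.b.data = np.zeros(4)
        x = np.array([[0.5, 1.0, 0.0, 2.0]])
        assert np.allclose(enc(x).data, x)

    def test_zero_input_zero_bias_gives_zero(self):
        rng = np.random.default_rng(10)
        enc = TabularEncoder(4, small_cfg(), rng)
        enc.lin.b.data[:] = 0.0
        assert np.allclose(enc(np.zeros((1, 4))).data, 0.0)

    def test_outputs_nonnegative(self, rng):
        enc = TabularEncoder(6, small_cfg(), np.random.default_rng(11))
        assert (enc(rng.standard_normal((8, 6))).data >= 0).all()

    def test_nan_rejected(self):
        enc = TabularEncoder(3, small_cfg(), np.random.default_rng(12))
        with pytest.raises(ValidationError):
            enc(np.array([[1.0, np.nan, 0.0]]))

    def test_dimension_mismatch_rejected(self):
        enc = TabularEncoder(3, small_cfg(), np.random.default_rng(13))
        with pytest.raises(ValidationError):
            enc(np.ones((1, 5)))


class TestProjection:
    def _bank(self, samples, names):
        schema = infer_schema(names, samples)
        return MultimodalEncoder(names, schema, small_cfg(),
                                 np.random.default_rng(14))

    def test_all_modalities_project_to_unified_dim(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        bank = self._bank(samples, manifest.modality_names)
        embs = bank.encode_sample(samples[0])
        assert {e.projected.shape for e in embs} == {(16,)}

    def test_projection_is_linear_with_zero_bias(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        bank = self._bank(samples, manifest.modality_names)
        proj = bank.projections["transcriptomics"]
        proj.b.data[:] = 0.0
        z = Tensor(np.random.default_rng(15).standard_normal((2, proj.W.shape[0])))
        assert np.allclose(bank.project("transcriptomics", z * 3.0).data,
                           3.0 * bank.project("transcriptomics", z).data)

    def test_unknown_modality_rejected(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        bank = self._bank(samples, manifest.modality_names)
        with pytest.raises(ValidationError):
            bank.project("smiles", Tensor(np.zeros((1, 8))))


class TestEncodeSample:
    def test_only_available_modalities_encoded(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        names = manifest.modality_names
        bank = MultimodalEncoder(names, infer_schema(names, samples),
                                 small_cfg(), np.random.default_rng(16))
        s = samples[0]
        s2 = type(s)(sample_id=s.sample_id,
                     payloads={names[0]: s.payloads[names[0]],
                               names[2]: s.payloads[names[2]]},
                     availability={names[0]: 1, names[1]: 0, names[2]: 1},
                     label=s.label)
        embs = bank.encode_sample(s2)
        assert [e.name for e in embs] == [names[0], names[2]]
        assert [e.modality_id for e in embs] == [1, 3]

    def test_deterministic_when_stochastic_off(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        names = manifest.modality_names
        bank = MultimodalEncoder(names, infer_schema(names, samples),
                                 small_cfg(), np.random.default_rng(17))
        a = bank.encode_sample(samples[0])
        b = bank.encode_sample(samples[0])
        for ea, eb in zip(a, b):
            assert (ea.projected == eb.projected).all()

    def test_stochastic_passes_differ(self, mixed_modalities):
        manifest, samples, _ = mixed_modalities
        names = manifest.modality_names
        bank = MultimodalEncoder(names, infer_schema(names, samples),
                                 small_cfg(), np.random.default_rng(18))
        srng = np.random.default_rng(19)
        a = bank.encode_sample(samples[0], stochastic_rng=srng)
        b = bank.encode_sample(samples[0], stochastic_rng=srng)
        assert any((ea.projected != eb.projected).any() for ea, eb in zip(a, b))
        assert all(e.stochastic for e in a)


def test_token_batch_right_pads():
    batch = build_token_batch([np.array([1, 2, 3]), np.array([1, 5])])
    assert batch.tolist() == [[1, 2, 3], [1, 5, 0]]
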