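"""Modality-specific encoders and the unified projection.

Each modality family has a dedicated trainable encoder mapping its payload to
a latent vector ``z_k``:

* structural (molecular graph) — an edge-aware message-passing network:
  ``h_v ← ReLU(W1 h_v + Σ_{u∈N(v)} ψ(h_u, e_uv))`` for T rounds, followed by a
  permutation-invariant READOUT (mean, sum or attention pooling);
* sequential (SMILES, protein) — token embedding + fixed sinusoidal positions,
  a small self-attention encoder with padding masked, pooled as the CLS state
  combined with an elementwise max over non-pad positions;
* tabular (transcriptomics, bioassay) — a single ReLU layer with dropout;
* precomputed embeddings (text) — a pass-through that only applies dropout in
  stochastic mode.

All latents are then projected by per-modality affine maps ``π_k`` into one
shared d-dimensional space; fusion only ever sees projected vectors.

Dropout is the single source of encoder stochasticity: passing ``rng=None``
gives deterministic outputs, passing a generator enables the noise used both
for regularization and for Monte-Carlo uncertainty passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, relu, scatter_add_rows
from .datamodel import (
    MODALITY_FAMILIES,
    MolecularGraph,
    MultimodalSample,
    ValidationError,
    Vocab,
)
from .io import tokenize
from .nn import (
    MLP,
    Dropout,
    Embedding,
    Linear,
    Module,
    Parameter,
    TransformerLayer,
    sinusoidal_positions,
)

__all__ = [
    "EncoderConfig",
    "ModalityEmbedding",
    "GraphBatch",
    "build_graph_batch",
    "build_token_batch",
    "GraphEncoder",
    "SequenceEncoder",
    "TabularEncoder",
    "PassthroughEncoder",
    "MultimodalEncoder",
]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters (defaults follow the tuned configuration:
    unified dimension 256, 3 GNN layers, 8 attention heads, dropout 0.3)."""

    unified_dim: int = 256
    gnn_layers: int = 3
    graph_hidden: int = 64
    attention_heads: int = 8
    seq_d_model: int = 64
    seq_layers: int = 1
    seq_max_len: int = 128
    tabular_latent: int = 128
    dropout_rate: float = 0.3
    readout: str = "mean"          # {mean, sum, attention}
    cls_combine: str = "sum"       # {sum, concat}

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.readout not in ("mean", "sum", "attention"):
            raise ValidationError(f"unknown readout {self.readout!r}")
        if self.cls_combine not in ("sum", "concat"):
            raise ValidationError(f"unknown cls_combine {self.cls_combine!r}")
        if min(self.unified_dim, self.graph_hidden, self.seq_d_model,
               self.tabular_latent) <= 0:
            raise ValidationError("all dimensions must be positive")


@dataclass
class ModalityEmbedding:
    """Latent + unified-space embedding of one modality of one sample."""

    modality_id: int
    name: str
    latent: np.ndarray     # z_k, dimension d_k
    projected: np.ndarray  # z̃_k = π_k(z_k), dimension d
    stochastic: bool = False


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Disjoint union of graphs with directed edge arrays (each undirected
    edge appears in both directions) and a node→graph index."""

    node_features: np.ndarray  # (N, d_v)
    src: np.ndarray            # (2E,)
    dst: np.ndarray            # (2E,)
    edge_features: np.ndarray  # (2E, d_e)
    graph_index: np.ndarray    # (N,)
    n_graphs: int

    @property
    def node_counts(self) -> np.ndarray:
        return np.bincount(self.graph_index, minlength=self.n_graphs)


def build_graph_batch(graphs: list[MolecularGraph]) -> GraphBatch:
    feats, srcs, dsts, efeats, gidx = [], [], [], [], []
    offset = 0
    d_e = max((g.edge_features.shape[1] for g in graphs if g.n_edges), default=1)
    for gi, g in enumerate(graphs):
        feats.append(g.node_features)
        gidx.append(np.full(g.n_nodes, gi))
        if g.n_edges:
            u, v = g.edge_list[:, 0] + offset, g.edge_list[:, 1] + offset
            srcs.extend([u, v])
            dsts.extend([v, u])
            efeats.extend([g.edge_features, g.edge_features])
        offset += g.n_nodes
    return GraphBatch(
        node_features=np.concatenate(feats, axis=0),
        src=np.concatenate(srcs) if srcs else np.zeros(0, np.int64),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, np.int64),
        edge_features=np.concatenate(efeats, axis=0) if efeats else np.zeros((0, d_e)),
        graph_index=np.concatenate(gidx),
        n_graphs=len(graphs),
    )


def build_token_batch(seqs: list[np.ndarray]) -> np.ndarray:
    """Right-pad integer id sequences into a (B, L_max) matrix (pad id 0)."""
    L = max(len(s) for s in seqs)
    out = np.zeros((len(seqs), L), dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class GraphEncoder(Module):
    """Edge-aware message passing with per-layer parameters.

    The message function ψ is a one-hidden-layer perceptron over the
    concatenated neighbour state and edge feature; the empty neighbourhood
    contributes a zero message sum.
    """

    def __init__(self, d_v: int, d_e: int, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.graph_hidden
        self.in_proj = Linear(d_v, h, rng)
        self.self_layers = [Linear(h, h, rng) for _ in range(cfg.gnn_layers)]
        self.msg_layers = [MLP([h + d_e, h, h], rng) for _ in range(cfg.gnn_layers)]
        self.dropout = Dropout(cfg.dropout_rate)
        self.readout = cfg.readout
        if cfg.readout == "attention":
            self.attn_vec = Parameter(rng.standard_normal(h) / np.sqrt(h))
        self.latent_dim = h

    def __call__(self, batch: GraphBatch, rng: np.random.Generator | None = None) -> Tensor:
        h = self.in_proj(Tensor(batch.node_features))
        n_nodes = batch.node_features.shape[0]
        e = Tensor(batch.edge_features)
        for w_self, w_msg in zip(self.self_layers, self.msg_layers):
            if batch.src.size:
                msg_in = concat([gather_rows(h, batch.src), e], axis=-1)
                msg = w_msg(msg_in, rng=None)
                agg = scatter_add_rows(msg, batch.dst, n_nodes)
            else:
                agg = Tensor(np.zeros((n_nodes, self.latent_dim)))
            h = relu(w_self(h) + agg)
            h = self.dropout(h, rng)
        return self._readout(h, batch)

    def _readout(self, h: Tensor, batch: GraphBatch) -> Tensor:
        pooled = scatter_add_rows(h, batch.graph_index, batch.n_graphs)
        if self.readout == "sum":
            return pooled
        if self.readout == "mean":
            return pooled * Tensor(1.0 / batch.node_counts[:, None])
        # attention pooling: per-graph softmax over node scores
        scores = h @ self.attn_vec  # (N,)
        shift = np.zeros(batch.n_graphs)
        np.maximum.at(shift, batch.graph_index, scores.data)
        ex = (scores - Tensor(shift[batch.graph_index])).exp()
        denom = scatter_add_rows(ex.reshape(-1, 1), batch.graph_index, batch.n_graphs)
        alpha = ex.reshape(-1, 1) / gather_rows(denom, batch.graph_index)
        return scatter_add_rows(h * alpha, batch.graph_index, batch.n_graphs)


class SequenceEncoder(Module):
    """Self-attention encoder over token ids; CLS + masked max-pool readout."""

    def __init__(self, vocab_size: int, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.seq_d_model
        self.embed = Embedding(vocab_size, d, rng)
        self.positions = sinusoidal_positions(cfg.seq_max_len, d)
        self.layers = [TransformerLayer(d, cfg.attention_heads, rng,
                                        dropout=cfg.dropout_rate)
                       for _ in range(cfg.seq_layers)]
        self.cls_combine = cfg.cls_combine
        self.latent_dim = d if cfg.cls_combine == "sum" else 2 * d

    def __call__(self, tokens: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        tokens = np.atleast_2d(tokens)
        mask = tokens != 0  # pad id is 0
        if not mask.any(axis=1).all():
            raise ValidationError("all-pad token sequence")
        x = self.embed(tokens) + Tensor(self.positions[: tokens.shape[1]])
        for layer in self.layers:
            x = layer(x, key_mask=mask, rng=rng)
        cls = x[:, 0, :]
        neg = np.where(mask, 0.0, -1e30)[:, :, None]
        maxpool = (x + Tensor(neg)).max(axis=1)
        if self.cls_combine == "sum":
            return cls + maxpool
        return concat([cls, maxpool], axis=-1)

    @staticmethod
    def max_pool(hidden: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Elementwise max over non-pad positions of precomputed hidden states
        (the pooling operator in isolation; monotone in added positions)."""
        masked = np.where(mask[:, :, None], hidden, -np.inf)
        return masked.max(axis=1)


class TabularEncoder(Module):
    """z = Dropout(ReLU(W x + b)); rejects NaN inputs."""

    def __init__(self, d_in: int, cfg: EncoderConfig, rng: np.random.Generator,
                 latent: int | None = None):
        self.lin = Linear(d_in, latent or cfg.tabular_latent, rng)
        self.dropout = Dropout(cfg.dropout_rate)
        self.d_in = d_in
        self.latent_dim = latent or cfg.tabular_latent

    def __call__(self, x: np.ndarray | Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = np.atleast_2d(np.asarray(x, dtype=np.float64))
            if np.isnan(x).any():
                raise ValidationError("NaN in tabular input; impute or mark missing")
            if x.shape[-1] != self.d_in:
                raise ValidationError(f"expected dim {self.d_in}, got {x.shape[-1]}")
            x = Tensor(x)
        return self.dropout(relu(self.lin(x)), rng)


class PassthroughEncoder(Module):
    """Identity encoder for precomputed embedding vectors; dropout is applied
    only in stochastic mode so Monte-Carlo uncertainty remains defined."""

    def __init__(self, d_in: int, cfg: EncoderConfig):
        self.d_in = d_in
        self.latent_dim = d_in
        self.dropout = Dropout(cfg.dropout_rate)

    def __call__(self, x: np.ndarray | Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = np.atleast_2d(np.asarray(x, dtype=np.float64))
            if np.isnan(x).any():
                raise ValidationError("NaN in embedding input")
            x = Tensor(x)
        return self.dropout(x, rng)


# ---------------------------------------------------------------------------
# The multimodal encoder bank
# ---------------------------------------------------------------------------

@dataclass
class ModalitySchema:
    """Input dimensions for one modality, inferred from the dataset."""

    name: str
    family: str
    tabular_dim: int = 0
    d_v: int = 0
    d_e: int = 0
    vocab: Vocab | None = None


def infer_schema(modality_names: list[str], samples: list[MultimodalSample],
                 train_only_vocab: bool = True) -> dict[str, ModalitySchema]:
    """Inspect samples to size each encoder; vocabularies are fit on the
    training split only."""
    schema: dict[str, ModalitySchema] = {}
    for name in modality_names:
        fam = MODALITY_FAMILIES[name]
        ms = ModalitySchema(name=name, family=fam)
        payloads = [(s.split, s.payloads[name]) for s in samples
                    if s.availability.get(name)]
        if not payloads:
            raise ValidationError(f"modality {name!r} has no available payloads")
        if fam == "tabular":
            ms.tabular_dim = payloads[0][1].shape[0]
        elif name == "graph":
            g = payloads[0][1]
            ms.d_v = g.node_features.shape[1]
            ms.d_e = g.edge_features.shape[1] if g.edge_features.size else 1
        else:
            strings = [p for split, p in payloads
                       if split == "train" or not train_only_vocab]
            if not strings:
                strings = [p for _, p in payloads]
            ms.vocab = Vocab.fit(strings, name)
        schema[name] = ms
    return schema


class MultimodalEncoder(Module):
    """One encoder + unified projection per declared modality."""

    def __init__(self, modality_names: list[str], schema: dict[str, ModalitySchema],
                 cfg: EncoderConfig, rng: np.random.Generator,
                 shared_encoder: bool = False):
        self.modality_names = list(modality_names)
        self.cfg = cfg
        self.shared = shared_encoder
        self.encoders: dict[str, Module] = {}
        self.projections: dict[str, Linear] = {}
        if shared_encoder:
            # ablation: every modality flattened to a vector through one MLP
            self._shared_dim = max(self._flat_dim(schema[n]) for n in modality_names)
            shared = MLP([self._shared_dim, cfg.tabular_latent, cfg.tabular_latent],
                         rng, dropout=cfg.dropout_rate, final_activation=True)
            for name in modality_names:
                self.encoders[name] = shared
                self.projections[name] = Linear(cfg.tabular_latent, cfg.unified_dim, rng)
            self._schema = schema
            return
        for name in modality_names:
            ms = schema[name]
            if name == "graph":
                enc: Module = GraphEncoder(ms.d_v, ms.d_e, cfg, rng)
            elif ms.family == "sequential":
                enc = SequenceEncoder(len(ms.vocab), cfg, rng)
            elif name == "text_embedding":
                enc = PassthroughEncoder(ms.tabular_dim, cfg)
            else:
                enc = TabularEncoder(ms.tabular_dim, cfg, rng)
            self.encoders[name] = enc
            self.projections[name] = Linear(enc.latent_dim, cfg.unified_dim, rng)
        self._schema = schema

    # -- flattening for the shared-encoder ablation --------------------------
    @staticmethod
    def _flat_dim(ms: ModalitySchema) -> int:
        if ms.family == "tabular":
            return ms.tabular_dim
        if ms.name == "graph":
            return ms.d_v
        return len(ms.vocab)

    def _flatten(self, name: str, payload) -> np.ndarray:
        ms = self._schema[name]
        if ms.family == "tabular":
            v = payload
        elif name == "graph":
            v = payload.node_features.mean(axis=0)
        else:  # token histogram, length-normalized
            ids = payload if isinstance(payload, np.ndarray) else self.token_ids(name, payload)
            v = np.bincount(ids[ids != 0], minlength=len(ms.vocab)).astype(np.float64)
            v /= max(v.sum(), 1.0)
        out = np.zeros(self._shared_dim)
        out[: v.shape[0]] = v
        return out

    # -- tokenization helper (cached per call site) ---------------------------
    def token_ids(self, name: str, s: str) -> np.ndarray:
        return tokenize(s, name, self._schema[name].vocab,
                        max_len=self.cfg.seq_max_len).token_ids

    # -- batch encoding -------------------------------------------------------
    def encode_modality(self, name: str, payloads: list,
                        rng: np.random.Generator | None = None) -> Tensor:
        """Encode a homogeneous list of payloads -> latent (n, d_k)."""
        enc = self.encoders[name]
        if self.shared:
            x = np.stack([self._flatten(name, p) for p in payloads])
            return enc(Tensor(x), rng=rng)
        fam = self._schema[name].family
        if name == "graph":
            return enc(build_graph_batch(payloads), rng=rng)
        if fam == "sequential":
            ids = [p if isinstance(p, np.ndarray) else self.token_ids(name, p)
                   for p in payloads]
            return enc(build_token_batch(ids), rng=rng)
        return enc(np.stack([np.asarray(p, dtype=np.float64) for p in payloads]), rng=rng)

    def project(self, name: str, latent: Tensor) -> Tensor:
        if name not in self.projections:
            raise ValidationError(f"unknown modality {name!r}")
        return self.projections[name](latent)

    def encode_batch(self, samples: list[MultimodalSample], delta: np.ndarray,
                     rng: np.random.Generator | None = None
                     ) -> tuple[dict[str, Tensor], dict[str, Tensor]]:
        """Encode available modalities of a batch.

        Returns (projected, latents): per modality a (B, d) tensor whose rows
        for unavailable samples are zero — those rows carry attention weight
        exactly 0 downstream, so their value never matters.
        """
        B = len(samples)
        projected: dict[str, Tensor] = {}
        latents: dict[str, Tensor] = {}
        for k, name in enumerate(self.modality_names):
            rows = np.nonzero(delta[:, k])[0]
            if rows.size == 0:
                d = self.projections[name].W.shape
                latents[name] = Tensor(np.zeros((B, d[0])))
                projected[name] = Tensor(np.zeros((B, d[1])))
                continue
            z = self.encode_modality(name, [samples[i].payloads[name] for i in rows],
                                     rng=rng)
            zt = self.project(name, z)
            latents[name] = scatter_add_rows(z, rows, B)
            projected[name] = scatter_add_rows(zt, rows, B)
        return projected, latents

    def encode_sample(self, sample: MultimodalSample,
                      stochastic_rng: np.random.Generator | None = None
                      ) -> list[ModalityEmbedding]:
        """Embeddings for the available modalities of one sample (inspection
        API; training uses :meth:`encode_batch`)."""
        out = []
        for k, name in enumerate(self.modality_names):
            if not sample.availability.get(name):
                continue
            z = self.encode_modality(name, [sample.payloads[name]], rng=stochastic_rng)
            zt = self.project(name, z)
            out.append(ModalityEmbedding(
                modality_id=k + 1, name=name,
                latent=z.data[0], projected=zt.data[0],
                stochastic=stochastic_rng is not None))
        return out
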