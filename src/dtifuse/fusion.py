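"""Hierarchical cross-modal fusion with availability masking.

Two-stage fusion: modalities are grouped into semantic clusters; within each
cluster an availability-masked softmax attention (query vector learned per
cluster) produces a cluster vector

    α_k = δ_k · exp(q_jᵀ z̃_k) / Σ_{k'} δ_{k'} · exp(q_jᵀ z̃_{k'}),
    u_j = Σ_k α_k z̃_k,

so only present modalities participate and their weights renormalize over the
present subset.  Cluster vectors then pass through a small self-attention
encoder with a learned CLS slot and *no* positional encoding — the global
stage is therefore cluster-order invariant by construction — and the final
vector is an affine map of [CLS(H) ‖ Mean(H)] back to dimension d.

A flat single-softmax fusion over all modalities is kept as the ablation
path, and scalar cosine alignment diagnostics live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, softmax, stack
from .datamodel import ValidationError
from .nn import Linear, Module, Parameter, TransformerLayer

__all__ = [
    "ClusterLayout",
    "AttentionRecord",
    "FusionResult",
    "masked_intra_cluster_attention",
    "flat_softmax_fusion",
    "alignment_score",
    "check_alignment_margin",
    "HierarchicalFusion",
    "FlatFusion",
]

#: default semantic grouping; restricted to the modalities a dataset declares
DEFAULT_CLUSTERS = {
    "chemical": ["graph", "smiles"],
    "biological": ["protein_seq", "transcriptomics"],
    "evidence": ["bioassay", "text_embedding"],
}


@dataclass
class ClusterLayout:
    """Partition of declared modality names into named semantic clusters."""

    clusters: dict[str, list[str]]

    def __post_init__(self):
        all_members = [m for ms in self.clusters.values() for m in ms]
        if len(set(all_members)) != len(all_members):
            raise ValidationError("clusters must be disjoint")
        if any(not ms for ms in self.clusters.values()):
            raise ValidationError("empty cluster in layout")

    @classmethod
    def default(cls, modality_names: list[str]) -> "ClusterLayout":
        clusters = {}
        for cname, members in DEFAULT_CLUSTERS.items():
            hit = [m for m in modality_names if m in members]
            if hit:
                clusters[cname] = hit
        missing = [m for m in modality_names
                   if m not in {x for ms in clusters.values() for x in ms}]
        for m in missing:  # unknown names each get their own cluster
            clusters[m] = [m]
        return cls(clusters)

    def validate_covers(self, modality_names: list[str]) -> None:
        members = {m for ms in self.clusters.values() for m in ms}
        if members != set(modality_names):
            raise ValidationError(
                f"cluster layout covers {sorted(members)}, dataset declares "
                f"{sorted(modality_names)}")


@dataclass
class AttentionRecord:
    """One attention assignment: weights over participants, masked weights
    exactly zero, present weights summing to one."""

    level: str  # {intra_cluster, global, flat}
    participants: list[str]
    weights: np.ndarray

    def check(self, delta: np.ndarray | None = None) -> None:
        w = self.weights
        if (w < 0).any():
            raise AssertionError("negative attention weight")
        if delta is not None:
            if not np.allclose(w[delta == 0], 0.0):
                raise AssertionError("masked participant received nonzero weight")
        if not np.allclose(w.sum(), 1.0, atol=1e-6):
            raise AssertionError(f"weights sum to {w.sum()}, expected 1")


@dataclass
class FusionResult:
    cluster_vectors: dict[str, np.ndarray]
    fused: np.ndarray
    trace: list[AttentionRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reference (numpy, single-sample) operations — the auditable definitions
# ---------------------------------------------------------------------------

def masked_intra_cluster_attention(embeddings: np.ndarray, delta: np.ndarray,
                                   query: np.ndarray,
                                   participants: list[str] | None = None,
                                   ) -> tuple[np.ndarray, AttentionRecord]:
    """Availability-masked softmax attention over one cluster's modalities.

    ``embeddings``: (n_members, d); ``delta``: (n_members,) in {0,1};
    ``query``: (d,).  Logits are max-subtracted before exponentiation.
    """
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    delta = np.asarray(delta, dtype=np.float64)
    if delta.sum() == 0:
        raise ValidationError("all modalities in cluster are missing; skip the cluster")
    logits = embeddings @ np.asarray(query, dtype=np.float64)
    shifted = logits - logits[delta > 0].max()
    ex = delta * np.exp(shifted)
    alpha = ex / ex.sum()
    fused = alpha @ embeddings
    names = participants or [f"m{k+1}" for k in range(len(delta))]
    record = AttentionRecord("intra_cluster", names, alpha)
    record.check(delta)
    return fused, record


def flat_softmax_fusion(embeddings: np.ndarray, delta: np.ndarray,
                        weight: np.ndarray,
                        participants: list[str] | None = None,
                        ) -> tuple[np.ndarray, AttentionRecord]:
    """Single softmax over all available modalities: α_k ∝ δ_k·exp(wᵀz̃_k)."""
    fused, record = masked_intra_cluster_attention(embeddings, delta, weight,
                                                   participants)
    return fused, AttentionRecord("flat", record.participants, record.weights)


def alignment_score(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; symmetric and scale invariant."""
    z_i, z_j = np.asarray(z_i, np.float64), np.asarray(z_j, np.float64)
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0.0 or nj == 0.0:
        raise ValidationError("alignment_score undefined for zero vectors")
    return float(np.clip(z_i @ z_j / (ni * nj), -1.0, 1.0))


def check_alignment_margin(batch: dict[str, np.ndarray], reference: str,
                           margin: float) -> dict[str, dict]:
    """Mean pairwise cosine alignment of each support modality against the
    reference modality, with a pass/fail flag against the margin.

    Diagnostic only — alignment is *enforced* by the contrastive loss, this
    merely monitors the stated inequality E[A(z_ref, z_k)] ≥ margin.
    """
    if not batch:
        raise ValidationError("empty batch")
    ref = batch[reference]
    out: dict[str, dict] = {}
    for name, z in batch.items():
        if name == reference:
            continue
        scores = [alignment_score(ref[i], z[i]) for i in range(ref.shape[0])]
        mean = float(np.mean(scores))
        out[name] = {"mean_alignment": mean, "passes": mean >= margin}
    return out


# ---------------------------------------------------------------------------
# Trainable fusion modules (batched, autodiff)
# ---------------------------------------------------------------------------

_NEG = -1e30


def _masked_weights(logit_cols: list[Tensor], mask: np.ndarray,
                    reweight: Tensor | None = None) -> Tensor:
    """Batched masked softmax: columns are per-member logits (B,), ``mask``
    (B, n) availability, optional multiplicative ``reweight`` (B, n) ≥ 0."""
    logits = stack(logit_cols, axis=1)  # (B, n)
    bias = np.where(mask > 0, 0.0, _NEG)
    w = softmax(logits + Tensor(bias), axis=1)
    if reweight is not None:
        w = w * reweight
        denom = w.sum(axis=1, keepdims=True)
        safe = Tensor(np.where(denom.data > 0, 1.0, 0.0)) / (
            denom + Tensor((denom.data == 0).astype(np.float64)))
        w = w * safe
    return w


class HierarchicalFusion(Module):
    """Two-stage fusion; optional per-modality reweighting (the curriculum
    weights) is applied inside each cluster and renormalized there."""

    def __init__(self, modality_names: list[str], d: int, layout: ClusterLayout,
                 rng: np.random.Generator, n_heads: int = 4):
        layout.validate_covers(modality_names)
        self.modality_names = list(modality_names)
        self.layout = layout
        self.queries = {cname: Parameter(rng.standard_normal(d) / np.sqrt(d))
                        for cname in layout.clusters}
        self.cls_slot = Parameter(rng.standard_normal(d) / np.sqrt(d))
        self.global_layer = TransformerLayer(d, n_heads, rng)
        self.out = Linear(2 * d, d, rng)
        self.d = d

    def __call__(self, projected: dict[str, Tensor], delta: np.ndarray,
                 reweight: Tensor | None = None,
                 collect_trace: bool = False
                 ) -> tuple[Tensor, list[AttentionRecord]]:
        """projected: modality name -> (B, d); delta: (B, K) availability;
        reweight: optional (B, K) non-negative modality weights."""
        B = delta.shape[0]
        name_to_col = {n: k for k, n in enumerate(self.modality_names)}
        cluster_vecs: list[Tensor] = []
        present_cols: list[np.ndarray] = []
        trace: list[AttentionRecord] = []

        for cname, members in self.layout.clusters.items():
            cols = [name_to_col[m] for m in members]
            mask = delta[:, cols].astype(np.float64)
            if reweight is not None:
                rw = stack([reweight[:, c] for c in cols], axis=1)
                eff = mask * (rw.data > 0)
            else:
                rw = None
                eff = mask
            present = eff.any(axis=1)  # (B,) cluster survives for these rows
            q = self.queries[cname]
            logit_cols = [projected[m] @ q for m in members]
            # rows with no surviving member: weights all zero (handled below)
            safe_mask = np.where(present[:, None], eff, 1.0)  # avoid empty softmax
            w = _masked_weights(logit_cols, safe_mask, rw)
            w = w * Tensor(present[:, None].astype(np.float64))
            u = None
            for i, m in enumerate(members):
                term = projected[m] * w[:, i].reshape(B, 1)
                u = term if u is None else u + term
            cluster_vecs.append(u)
            present_cols.append(present)
            if collect_trace:
                for b in range(B):
                    rec = AttentionRecord("intra_cluster", members, w.data[b])
                    trace.append(rec)

        # global stage: CLS slot + one cluster slot each, no positions
        m = len(cluster_vecs)
        cls = Tensor(np.ones((B, 1, 1))) * self.cls_slot.reshape(1, 1, self.d)
        U = stack(cluster_vecs, axis=1)  # (B, m, d)
        seq = concat([cls, U], axis=1)   # (B, m+1, d)
        present_mat = np.stack(present_cols, axis=1)  # (B, m)
        key_mask = np.concatenate([np.ones((B, 1), bool), present_mat > 0], axis=1)
        H = self.global_layer(seq, key_mask=key_mask)
        cls_out = H[:, 0, :]
        # mean over present clusters only
        pm = present_mat.astype(np.float64)
        counts = np.maximum(pm.sum(axis=1, keepdims=True), 1.0)
        mean_out = None
        for j in range(m):
            term = H[:, j + 1, :] * Tensor(pm[:, j : j + 1] / counts)
            mean_out = term if mean_out is None else mean_out + term
        z = self.out(concat([cls_out, mean_out], axis=-1))
        return z, trace


class FlatFusion(Module):
    """Single masked softmax over all modalities (ablation of the hierarchy);
    the same optional reweighting applies multiplicatively."""

    def __init__(self, modality_names: list[str], d: int, rng: np.random.Generator):
        self.modality_names = list(modality_names)
        self.w = Parameter(rng.standard_normal(d) / np.sqrt(d))

    def __call__(self, projected: dict[str, Tensor], delta: np.ndarray,
                 reweight: Tensor | None = None,
                 collect_trace: bool = False
                 ) -> tuple[Tensor, list[AttentionRecord]]:
        B = delta.shape[0]
        logit_cols = [projected[m] @ self.w for m in self.modality_names]
        w = _masked_weights(logit_cols, delta.astype(np.float64), reweight)
        z = None
        for i, m in enumerate(self.modality_names):
            term = projected[m] * w[:, i].reshape(B, 1)
            z = term if z is None else z + term
        trace = []
        if collect_trace:
            trace = [AttentionRecord("flat", self.modality_names, w.data[b])
                     for b in range(B)]
        return z, trace
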