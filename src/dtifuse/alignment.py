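"""Cross-modal contrastive alignment and stochastic modality dropout.

The alignment loss is a symmetric InfoNCE over cosine similarities: for every
sample and every unordered pair (i, j) of its available modalities, the
positive is the same sample's (i, j) embedding pair and the negatives are the
same modality pair's embeddings of the *other* samples in the batch,

    -log  exp(sim(z_i, z_j)/τ) / Σ_b exp(sim(z_i, z_j^(b))/τ),

symmetrized over both anchor directions and averaged over all contributing
terms.  Pairs with a missing member contribute nothing.

Modality dropout thins the availability mask during training with per-modality
Bernoulli draws, re-drawing any row that would lose all modalities; the
inference path never calls it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .datamodel import ValidationError

__all__ = [
    "ContrastiveConfig",
    "DropoutSchedule",
    "contrastive_align_loss",
    "sample_modality_dropout",
]


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5     # τ_c, softmax temperature on cosine sims
    weight: float = 0.5          # λ, contribution to the total loss
    pair_policy: str = "all_pairs"  # or "reference_anchored"
    reference: str | None = None    # anchor modality for reference_anchored

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.weight < 0:
            raise ValidationError("contrastive weight must be non-negative")
        if self.pair_policy not in ("all_pairs", "reference_anchored"):
            raise ValidationError(f"unknown pair policy {self.pair_policy!r}")


@dataclass
class DropoutSchedule:
    drop_prob: float | tuple[float, ...] = 0.2  # p_k per modality (scalar = uniform)

    def probs(self, K: int) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.drop_prob, dtype=np.float64), (K,))
        if ((p < 0) | (p >= 1)).any():
            raise ValidationError("drop probabilities must be in [0, 1)")
        return p


def _normalize_rows(z: Tensor) -> Tensor:
    norms = (z * z).sum(axis=1, keepdims=True).sqrt()
    return z / (norms + 1e-12)


def contrastive_align_loss(projected: dict[str, Tensor], delta: np.ndarray,
                           modality_names: list[str],
                           config: ContrastiveConfig,
                           active: np.ndarray | None = None) -> Tensor:
    """Mean symmetric InfoNCE over modality pairs of a batch.

    ``projected``: modality -> (B, d); ``delta``: (B, K) effective
    availability; ``active``: optional (K,) curriculum mask — pairs with an
    inactive member are dropped from the loss.
    """
    B = delta.shape[0]
    if B < 2:
        raise ValidationError("contrastive loss needs a batch of at least 2")
    act = np.ones(len(modality_names), bool) if active is None else active.astype(bool)

    if config.pair_policy == "reference_anchored":
        ref = config.reference or modality_names[0]
        pairs = [(ref, m) for m in modality_names if m != ref]
    else:
        pairs = [(a, b) for ia, a in enumerate(modality_names)
                 for b in modality_names[ia + 1:]]

    total: Tensor | None = None
    n_terms = 0
    tau = config.temperature
    for a, b in pairs:
        ka, kb = modality_names.index(a), modality_names.index(b)
        if not (act[ka] and act[kb]):
            continue
        rows = np.nonzero(delta[:, ka] * delta[:, kb])[0]
        if rows.size < 2:  # no in-batch negatives exist for this pair
            continue
        za = _normalize_rows(projected[a][rows])
        zb = _normalize_rows(projected[b][rows])
        sims = (za @ zb.transpose(1, 0)) * (1.0 / tau)  # (n, n)
        n = rows.size
        eye = np.eye(n)
        # anchor a -> negatives are other samples' b embeddings (rows of sims)
        log_pa = softmax(sims, axis=1).log()
        log_pb = softmax(sims, axis=0).log()
        diag_a = (log_pa * Tensor(eye)).sum() * -1.0
        diag_b = (log_pb * Tensor(eye)).sum() * -1.0
        contrib = diag_a + diag_b
        total = contrib if total is None else total + contrib
        n_terms += 2 * n
    if n_terms == 0:
        return Tensor(0.0)
    return total * (1.0 / n_terms)


def sample_modality_dropout(delta: np.ndarray, schedule: DropoutSchedule,
                            rng: np.random.Generator) -> np.ndarray:
    """Training mask δ' = δ · Bernoulli(1 − p_k), rows re-drawn until at least
    one modality survives; δ' ≤ δ elementwise; missing data never resurrects."""
    delta = np.asarray(delta)
    if (~delta.any(axis=1)).any():
        raise ValidationError("every sample must have at least one available modality")
    p = schedule.probs(delta.shape[1])
    keep = rng.binomial(1, 1.0 - p, size=delta.shape)
    out = delta * keep
    bad = ~out.any(axis=1)
    while bad.any():
        keep = rng.binomial(1, 1.0 - p, size=(int(bad.sum()), delta.shape[1]))
        out[bad] = delta[bad] * keep
        bad = ~out.any(axis=1)
    return out
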