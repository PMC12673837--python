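"""The full predictive model: encoder bank → ACMO weighting → fusion → head.

Composition of the curriculum weights with hierarchical fusion: the composed
modality weights α̃ (availability × fading × confidence × task gate,
normalized over the active set) multiplicatively reweight each modality inside
its semantic cluster, where they are renormalized, and cluster fusion then
proceeds through the global attention stage.  In flat mode the fused vector is
directly Z = Σ_k α̃_k·π_k(z_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acmo import (
    CurriculumState,
    TaskModulation,
    UncertaintyConfig,
    compose_weights_tensor,
    estimate_uncertainty,
)
from .autodiff import Tensor
from .datamodel import MultimodalSample, ValidationError
from .encoders import EncoderConfig, ModalitySchema, MultimodalEncoder
from .fusion import AttentionRecord, ClusterLayout, FlatFusion, HierarchicalFusion
from .nn import MLP, Module

__all__ = ["ModelConfig", "DTIModel"]

FUSION_MODES = ("acmo_hierarchical", "acmo_flat", "flat")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion_mode: str = "acmo_hierarchical"
    cluster_layout: dict[str, list[str]] | None = None
    modulation_mode: str = "shared"
    modulation_penalty: float = 1e-3
    head_hidden: int = 64
    # ablation switches
    no_specific_encoders: bool = False
    no_hierarchical_fusion: bool = False
    no_task_modulation: bool = False

    def __post_init__(self):
        if self.fusion_mode not in FUSION_MODES:
            raise ValidationError(f"fusion_mode must be one of {FUSION_MODES}")


class DTIModel(Module):
    def __init__(self, modality_names: list[str], schema: dict[str, ModalitySchema],
                 cfg: ModelConfig, rng: np.random.Generator,
                 tasks: list[str] | None = None):
        self.modality_names = list(modality_names)
        self.cfg = cfg
        K, d = len(modality_names), cfg.encoder.unified_dim
        self.encoder = MultimodalEncoder(modality_names, schema, cfg.encoder, rng,
                                         shared_encoder=cfg.no_specific_encoders)
        layout = (ClusterLayout(cfg.cluster_layout) if cfg.cluster_layout
                  else ClusterLayout.default(modality_names))
        self.hier = HierarchicalFusion(modality_names, d, layout, rng)
        self.flat = FlatFusion(modality_names, d, rng)
        self.modulation = TaskModulation(K, d, rng, mode=cfg.modulation_mode,
                                         penalty_weight=cfg.modulation_penalty,
                                         tasks=tasks)
        self.head = MLP([d, cfg.head_hidden, 1], rng,
                        dropout=cfg.encoder.dropout_rate)
        self.K, self.d = K, d

    @property
    def effective_fusion_mode(self) -> str:
        return "flat" if self.cfg.no_hierarchical_fusion else self.cfg.fusion_mode

    def forward(self, samples: list[MultimodalSample], delta_eff: np.ndarray,
                state: CurriculumState, rng: np.random.Generator | None = None,
                task_id: str = "default", collect_trace: bool = False,
                ) -> tuple[Tensor, dict[str, Tensor], np.ndarray, list[AttentionRecord]]:
        """One forward pass.

        Returns (logits (B,), projected embeddings per modality, composed
        modality weights α̃ (B, K) as numpy, attention trace).
        """
        B = delta_eff.shape[0]
        projected, _ = self.encoder.encode_batch(samples, delta_eff, rng=rng)
        cols = [projected[m] for m in self.modality_names]

        if self.cfg.no_task_modulation:
            r: Tensor = Tensor(np.ones((B, self.K)))
        else:
            r = self.modulation.relevance(cols, task_id=task_id)

        c = np.broadcast_to(state.confidences, (B, self.K))
        alpha = compose_weights_tensor(delta_eff, state.beta, c, r, state.active)

        mode = self.effective_fusion_mode
        if mode == "acmo_hierarchical":
            z, trace = self.hier(projected, delta_eff, reweight=alpha,
                                 collect_trace=collect_trace)
        elif mode == "flat":
            z, trace = self.flat(projected, delta_eff, reweight=alpha,
                                 collect_trace=collect_trace)
        else:  # acmo_flat: Z = Σ α̃_k · π_k(z_k)
            z = None
            for i, m in enumerate(self.modality_names):
                term = projected[m] * alpha[:, i].reshape(B, 1)
                z = term if z is None else z + term
            trace = [AttentionRecord("flat", self.modality_names, alpha.data[b])
                     for b in range(B)] if collect_trace else []

        logits = self.head(z, rng=rng).reshape(B)
        return logits, projected, alpha.data, trace

    def modality_uncertainty(self, samples: list[MultimodalSample],
                             delta: np.ndarray, ucfg: UncertaintyConfig,
                             rng: np.random.Generator) -> np.ndarray:
        """Per-modality mean Monte-Carlo uncertainty over a probe batch.

        Measured on the raw encoder latents of the available samples of each
        modality; a modality with no available probe sample keeps u = 0.
        """
        u = np.zeros(self.K)
        for k, name in enumerate(self.modality_names):
            rows = np.nonzero(delta[:, k])[0]
            if rows.size == 0:
                continue
            payloads = [samples[i].payloads[name] for i in rows]

            def encode(x, r, _name=name):
                return self.encoder.encode_modality(_name, x, rng=r)

            _, u_rows = estimate_uncertainty(encode, payloads, ucfg, rng)
            u[k] = float(u_rows.mean())
        return u

    def modulation_penalty_term(self) -> Tensor:
        from .acmo import modulation_penalty

        if self.cfg.no_task_modulation:
            return Tensor(0.0)
        return modulation_penalty(self.modulation)
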