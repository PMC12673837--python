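"""Adaptive curriculum-guided modality optimization (ACMO).

The scheduler decides, at every curriculum step t, how much each modality
contributes to fusion.  Four ingredients compose multiplicatively:

* **uncertainty** u_k — empirical variance of S stochastic (Monte-Carlo
  dropout) encoder passes around their mean, u = (1/S)·Σ_s‖z^(s) − z̄‖²;
* **confidence** c_k = exp(−γ·u_k) ∈ (0, 1];
* **curriculum** — modalities ranked by descending confidence enter an active
  set whose size follows the sigmoid pacing P(t) = K/(1+exp(−η(t−t0)))
  (count = clamp(⌈P(t)⌉, 1, K)), and each newly activated modality ramps in
  linearly through a fading coefficient β_k(t) = min(1, max(0, (t−t_on)/τ));
* **task gate** r_k = σ(z̃_kᵀ T_k) (shared mode) or σ(z̃_kᵀ W t_T) (per-task
  mode), with an L2 penalty λ_mod·Σ_k‖T_k‖² on the task–modality matrix.

Final weights: α̃_k ∝ δ'_k · β_k · c_k · r_k over the active set, renormalized;
if masking empties the active set for a sample, the single highest-confidence
available modality gets weight 1 (a sample must never become unpredictable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, sigmoid
from .datamodel import ValidationError
from .nn import Module, Parameter

__all__ = [
    "UncertaintyConfig",
    "CurriculumConfig",
    "CurriculumState",
    "TaskModulation",
    "estimate_uncertainty",
    "confidence",
    "confidence_weights",
    "pacing",
    "update_schedule",
    "fading",
    "modulation_penalty",
    "compose_weights",
]


@dataclass
class UncertaintyConfig:
    n_passes: int = 8   # S, stochastic forward passes
    gamma: float = 1.0  # γ, confidence decay

    def __post_init__(self):
        if self.n_passes < 1:
            raise ValidationError("n_passes must be >= 1")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")


@dataclass
class CurriculumConfig:
    steepness: float = 1.0   # η
    midpoint: int = 10       # t0 (warm-up epochs)
    fade_window: int = 5     # τ_fade
    time_unit: str = "epoch"
    ema_decay: float = 0.9   # smoothing of batch-mean confidences

    def __post_init__(self):
        if self.steepness <= 0:
            raise ValidationError("steepness must be positive")
        if self.fade_window < 1:
            raise ValidationError("fade_window must be >= 1")
        if self.time_unit not in ("epoch", "step"):
            raise ValidationError("time_unit must be 'epoch' or 'step'")


@dataclass
class CurriculumState:
    """Scheduler state at curriculum time t (all arrays length K)."""

    K: int
    t: int = 0
    uncertainties: np.ndarray = None
    confidences: np.ndarray = None     # EMA batch-mean confidences
    ranking: np.ndarray = None         # π_t, permutation of 0..K-1
    active: np.ndarray = None          # bool mask A_t
    activation_time: np.ndarray = None # t_k^on, -1 while unset (immutable once set)
    beta: np.ndarray = None

    def __post_init__(self):
        K = self.K
        if self.uncertainties is None:
            self.uncertainties = np.zeros(K)
        if self.confidences is None:
            self.confidences = np.ones(K)
        if self.ranking is None:
            self.ranking = np.arange(K)
        if self.active is None:
            self.active = np.zeros(K, bool)
        if self.activation_time is None:
            self.activation_time = np.full(K, -1, dtype=np.int64)
        if self.beta is None:
            self.beta = np.zeros(K)

    def to_record(self, modality_names: list[str]) -> dict:
        return {
            "t": int(self.t),
            "u": {n: float(u) for n, u in zip(modality_names, self.uncertainties)},
            "c": {n: float(c) for n, c in zip(modality_names, self.confidences)},
            "ranking": [modality_names[i] for i in self.ranking],
            "active": [modality_names[i] for i in np.nonzero(self.active)[0]],
            "t_on": {n: int(t) for n, t in zip(modality_names, self.activation_time)},
            "beta": {n: float(b) for n, b in zip(modality_names, self.beta)},
        }


def estimate_uncertainty(encode, x, config: UncertaintyConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo mean and variance of a stochastic encoder.

    ``encode(x, rng)`` must return an (n, d) array-like for a batch ``x``;
    passing a generator enables its noise source.  Returns (z̄ (n, d),
    u (n,)) with u the mean squared deviation over the S passes (divisor S —
    the biased estimator, so E[u] = d·σ²·(S−1)/S for additive N(0, σ²I_d)
    noise).
    """
    S = config.n_passes
    passes = []
    for _ in range(S):
        z = encode(x, rng)
        z = z.data if isinstance(z, Tensor) else np.asarray(z, dtype=np.float64)
        passes.append(z)
    stackd = np.stack(passes)                      # (S, n, d)
    z_bar = stackd.mean(axis=0)
    u = ((stackd - z_bar) ** 2).sum(axis=-1).mean(axis=0)  # (n,)
    return z_bar, u


def confidence(u, gamma: float = 1.0):
    """c = exp(−γ·u) ∈ (0, 1]; γ = 0 disables uncertainty weighting."""
    u = np.asarray(u, dtype=np.float64)
    if (u < 0).any():
        raise ValidationError("uncertainty must be non-negative")
    out = np.exp(-gamma * u)
    return float(out) if out.ndim == 0 else out


def confidence_weights(c: np.ndarray, active: np.ndarray | None = None) -> np.ndarray:
    """Normalize confidences over the active set: α_k = c_k / Σ_{j∈A} c_j;
    weights are zero outside A."""
    c = np.asarray(c, dtype=np.float64)
    act = np.ones_like(c, bool) if active is None else np.asarray(active, bool)
    if not act.any():
        raise ValidationError("active set is empty")
    if (c[act] <= 0).any():
        raise ValidationError("confidences must be positive")
    w = np.where(act, c, 0.0)
    return w / w[act].sum()


def pacing(t: float, config: CurriculumConfig, K: int) -> int:
    """Number of active modalities at time t: clamp(⌈K·σ(η(t−t0))⌉, 1, K)."""
    if K < 1:
        raise ValidationError("K must be >= 1")
    raw = pacing_raw(t, config, K)
    return int(min(max(math.ceil(raw), 1), K))


def pacing_raw(t: float, config: CurriculumConfig, K: int) -> float:
    return K / (1.0 + math.exp(-config.steepness * (t - config.midpoint)))


def fading(t: float, t_on: int, fade_window: int) -> float:
    """Linear ramp β = min(1, max(0, (t − t_on)/τ)); unset activation → 0."""
    if t_on < 0:
        return 0.0
    return float(min(1.0, max(0.0, (t - t_on) / fade_window)))


def update_schedule(state: CurriculumState, new_confidence: np.ndarray, t: int,
                    config: CurriculumConfig) -> CurriculumState:
    """Advance the scheduler: EMA the confidences, rank descending (ties by
    ascending modality id), activate the top pacing(t) modalities, stamp
    first-activation times, refresh fading coefficients."""
    K = state.K
    new_confidence = np.asarray(new_confidence, dtype=np.float64)
    if new_confidence.shape != (K,):
        raise ValidationError(f"need confidences for all {K} modalities")
    if state.activation_time.max() >= 0 or state.t > 0:
        c = config.ema_decay * state.confidences + (1 - config.ema_decay) * new_confidence
    else:
        c = new_confidence.copy()
    # stable sort on (-c, id): descending confidence, ties broken by lower id
    ranking = np.lexsort((np.arange(K), -c))
    count = pacing(t, config, K)
    active = np.zeros(K, bool)
    active[ranking[:count]] = True
    t_on = state.activation_time.copy()
    newly = active & (t_on < 0)
    t_on[newly] = t
    beta = np.array([fading(t, t_on[k], config.fade_window) for k in range(K)])
    return CurriculumState(K=K, t=t, uncertainties=state.uncertainties,
                           confidences=c, ranking=ranking, active=active,
                           activation_time=t_on, beta=beta)


class TaskModulation(Module):
    """Task-conditioned relevance gates over modalities.

    Shared mode uses one row of the K×d matrix T per modality; per-task mode
    projects a registered task embedding through a shared d×d map W.
    """

    def __init__(self, K: int, d: int, rng: np.random.Generator,
                 mode: str = "shared", penalty_weight: float = 1e-3,
                 tasks: list[str] | None = None):
        if mode not in ("shared", "per_task"):
            raise ValidationError(f"unknown modulation mode {mode!r}")
        self.mode = mode
        self.penalty_weight = penalty_weight
        self.T = Parameter(rng.standard_normal((K, d)) * 0.01)
        self.W = Parameter(rng.standard_normal((d, d)) * (0.01 / math.sqrt(d)))
        self.task_embeddings = {t: Parameter(rng.standard_normal(d) * 0.01)
                                for t in (tasks or [])}
        self.K, self.d = K, d

    def relevance(self, projected_cols: list[Tensor],
                  task_id: str = "default") -> Tensor:
        """Gates r ∈ (0,1)^{B×K} from projected embeddings (list of (B, d))."""
        from .autodiff import stack

        if self.mode == "per_task":
            if task_id not in self.task_embeddings:
                raise ValidationError(f"task {task_id!r} not registered")
            t_vec = self.W @ self.task_embeddings[task_id]
            logits = [z @ t_vec for z in projected_cols]
        else:
            logits = [(z * self.T[k]).sum(axis=1)
                      for k, z in enumerate(projected_cols)]
        return sigmoid(stack(logits, axis=1))


def modulation_penalty(modulation: TaskModulation) -> Tensor:
    """L_mod = λ_mod · Σ_k ‖T_k‖²."""
    return (modulation.T * modulation.T).sum() * modulation.penalty_weight


def compose_weights(delta_eff: np.ndarray, beta: np.ndarray, c: np.ndarray,
                    r: np.ndarray, active: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Reference (numpy) weight composition.

    α̃_k = δ'_k·β_k·c_k·r_k / Σ_{j∈A} δ'_j·β_j·c_j·r_j for k ∈ A, else 0.
    Rows whose normalizer vanishes fall back to weight 1 on the single
    highest-confidence available modality.  Returns (α̃ (B, K), fallback mask
    (B,)).  With r constant and β ≡ 1 this reduces to pure confidence
    weighting; with β ≡ 1 it reduces to the confidence·relevance form.
    """
    delta_eff = np.atleast_2d(np.asarray(delta_eff, dtype=np.float64))
    B, K = delta_eff.shape
    beta = np.broadcast_to(np.asarray(beta, dtype=np.float64), (K,))
    c = np.broadcast_to(np.atleast_2d(np.asarray(c, dtype=np.float64)), (B, K))
    r = np.broadcast_to(np.atleast_2d(np.asarray(r, dtype=np.float64)), (B, K))
    act = np.asarray(active, bool)

    num = delta_eff * beta[None, :] * c * r * act[None, :]
    denom = num.sum(axis=1, keepdims=True)
    fallback = denom[:, 0] == 0.0
    alpha = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    if fallback.any():
        avail = delta_eff[fallback] > 0
        if not avail.any(axis=1).all():
            raise ValidationError("sample with no available modality in fallback")
        cf = np.where(avail, c[fallback], -np.inf)
        best = cf.argmax(axis=1)
        alpha[np.nonzero(fallback)[0], :] = 0.0
        alpha[np.nonzero(fallback)[0], best] = 1.0
    return alpha, fallback


def compose_weights_tensor(delta_eff: np.ndarray, beta: np.ndarray,
                           c: np.ndarray, r: Tensor, active: np.ndarray
                           ) -> Tensor:
    """Autodiff twin of :func:`compose_weights`: gradient flows through the
    task gates ``r`` only (δ', β, c are schedule constants).  Confidence rows
    are pre-scaled to max 1 — the ratio is unchanged, the normalizer cannot
    underflow."""
    delta_eff = np.atleast_2d(np.asarray(delta_eff, dtype=np.float64))
    B, K = delta_eff.shape
    c = np.broadcast_to(np.atleast_2d(np.asarray(c, dtype=np.float64)), (B, K))
    cmax = np.maximum(c.max(axis=1, keepdims=True), 1e-300)
    const = delta_eff * np.asarray(beta)[None, :] * (c / cmax) * \
        np.asarray(active, bool)[None, :]
    num = Tensor(const) * r
    denom = num.sum(axis=1, keepdims=True)
    fallback = denom.data[:, 0] <= 0.0
    extra = np.zeros((B, K))
    if fallback.any():
        avail = delta_eff[fallback] > 0
        cf = np.where(avail, c[fallback], -np.inf)
        best = cf.argmax(axis=1)
        extra[np.nonzero(fallback)[0], best] = 1.0
    num = num + Tensor(extra)
    return num / num.sum(axis=1, keepdims=True)
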