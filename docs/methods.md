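# Methods

## Model

A dataset declares K modalities (3–5 of: molecular graph, SMILES, protein
sequence, transcriptomics, bioassay, precomputed text embedding), each with a
per-sample availability bit δ_k. The model is a pipeline of four stages.

**Modality-specific encoders.** Graphs go through T rounds of edge-aware
message passing, h_v ← ReLU(W₁h_v + Σ_{u∈N(v)} ψ(h_u, e_uv)), where ψ is a
one-hidden-layer perceptron over the concatenated neighbour state and bond
feature; parameters are per-layer (not shared across rounds), and the
readout is mean pooling by default (sum and attention pooling are available).
Sequences are tokenized (atom-wise regex for SMILES — multi-character
elements, bracket atoms and ring digits are single tokens; one token per
amino acid for proteins), embedded with fixed sinusoidal positions, and
encoded by a small self-attention stack with padding masked; the sequence
representation is the CLS state plus the elementwise max over non-pad
positions (elementwise sum by default, concatenation available). Tabular
profiles use a single ReLU layer with dropout; precomputed text embeddings
pass through unchanged except for dropout in stochastic mode, so their
Monte-Carlo uncertainty stays defined. Pretrained language-model encoders
are out of scope; the text modality is therefore accepted only as
precomputed vectors, and all encoders here train from scratch at desk scale.
Every latent is projected by a per-modality affine map into one unified
d-dimensional space; fusion never sees raw latents.

**Hierarchical masked fusion.** Modalities group into semantic clusters
(default: chemical = {graph, smiles}, biological = {protein_seq,
transcriptomics}, evidence = {bioassay, text_embedding}; configurable).
Within a cluster, weights are an availability-masked softmax of q_jᵀz̃_k
(max-subtracted logits; masked members get weight exactly 0; weights over
present members sum to 1). Cluster vectors plus a learned CLS slot pass
through one self-attention layer *without positional encoding* — the global
stage is cluster-order invariant by construction — and the output is an
affine re-projection of [CLS ‖ mean-over-present-clusters] back to dimension
d, so downstream heads are fusion-mode agnostic. Clusters whose members are
all missing are skipped (masked out of the global stage), not zero-filled.
A flat single-softmax fusion over all modalities is retained as the
ablation path.

**Contrastive alignment.** For every sample and every unordered pair of its
available modalities, a symmetric InfoNCE term on cosine similarities
(temperature τ_c = 0.5) pulls the pair together against the same modality
pair of other batch samples; both anchor directions are averaged, pairs with
a missing member contribute nothing, and pairs whose member is outside the
curriculum-active set are excluded. All-pairs is the default policy; a
reference-anchored variant (all pairs against one designated modality) is
available. The alignment-margin inequality on mean cosine similarity is
implemented as a monitored diagnostic, not a loss term — the contrastive
loss already enforces alignment, and the margin statement has no penalty
form. Training-time modality dropout (Bernoulli, p = 0.2 per modality,
re-drawn so at least one modality survives per sample) simulates missing
data; inference never applies it.

**Curriculum-guided weighting.** Per epoch, S = 8 stochastic encoder passes
on a fixed probe batch give per-modality uncertainties
u_k = (1/S)Σ_s‖φ^{ω_s}(x_k) − z̄_k‖² (divisor S — the biased estimator, so an
identity-plus-N(0,σ²I_d) encoder has E[u] = d·σ²·(S−1)/S). Confidence is
c_k = exp(−γu_k); the curriculum ranks modalities by an exponential moving
average (decay 0.9) of these confidences, activates the top
clamp(⌈K·σ(η(t−t₀))⌉, 1, K) of them (ties broken by modality id), stamps
immutable activation times, and fades each new modality in linearly over
τ_fade epochs. Task gates r_k = σ(z̃_kᵀT_k) (shared mode; a per-task mode
projects registered task embeddings through a shared map) are the only
learned factor in the composed weight

    α̃_k ∝ δ′_k · β_k · c_k · r_k   over the active set,

so gradients flow through r while δ′, β, c are schedule constants. If
masking empties a sample's active set, the single highest-confidence
available modality gets weight 1 — a sample must never become unpredictable.

**Composition with fusion.** In `acmo_flat` mode the fused vector is
directly Z = Σ_k α̃_k·π_k(z_k); in `acmo_hierarchical` mode (default) α̃
multiplicatively reweights modalities inside their clusters (renormalized
within each cluster) before the global stage. Note the consequence: in a
layout where every cluster is a singleton, within-cluster renormalization
makes α̃ — and hence the task gates — inert at inference; analyses that
interrogate the composed weights themselves should use `acmo_flat`, where α̃
is exactly the fusion weight.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 3e-4, batch 128, up to 100
epochs, dropout 0.3, L2 coefficient 1e-5 on all parameters except the
task–modality matrix T, which carries its own penalty λ_mod·Σ‖T_k‖²
(λ_mod = 1e-3 by default; the two regularizers are kept disjoint to avoid
double-counting). An alternative preset (`table2`: lr 1e-4, batch 256) is
shipped for the second documented configuration. The loss is
L_task + λ·L_align + L_mod with λ = 0.5 and L_task binary cross-entropy on
logits (clipped at ±30 with a straight-through gradient) or MSE for
regression.

Two deliberate deviations from the most literal reading of the design:

* **Early stopping** (patience 10) monitors the *validation task loss*, not
  the total: the alignment term changes regime whenever the curriculum
  activates a modality (new pairs enter the loss), so totals are not
  comparable across epochs. Patience also only fires once the curriculum has
  saturated (all modalities active, β ≡ 1) — otherwise a 10-epoch warm-up
  plus a 10-epoch patience lets training stop at the exact moment
  integration begins.
* **Confidence granularity**: composed weights use per-epoch modality-level
  confidences (EMA of probe-batch means) rather than per-sample ones inside
  every minibatch — per-sample Monte-Carlo estimates at every step would
  multiply the step cost by S. The per-sample path exists in the API
  (`estimate_uncertainty` returns per-sample u) for analysis use.

One numerical choice matters for cross-modality comparability: raw MC
variance grows with activation magnitude and latent width, which differ per
encoder architecture, so the training loop feeds γ the *scale-normalized*
uncertainty u_k/ū (probe mean across modalities). This makes the confidence
decay dimensionless without changing the within-run ranking of a degraded
versus clean modality.

## Synthetic data

The generator plants a tunable signal so every mechanism is testable without
external data. Labels are Bernoulli(1/2) (or standard normal for
regression). Informative tabular modalities are y·effect_size·w_k + N(0,
σ_k²) along a fixed random unit direction; an informative graph modality is
an Erdős–Rényi graph (8–16 nodes, edge probability 0.3) whose mean node
feature is shifted by y·effect_size along a fixed direction, optionally with
a label shift of the edge probability itself (`graph_structure_shift`) —
structure no node-feature pooling can recover, which is what makes graph
encoders non-redundant in ablation comparisons; an informative sequence
modality draws letters from a label-tilted categorical distribution.
Non-informative modalities are shape-matched pure noise. Availability is
Bernoulli(1 − ρ_k) with all-missing rows re-drawn. The defaults (effect size
2, σ = 1, ρ up to 0.1–0.3, n = 900–2000) are the study conditions used
throughout the tests; problem sizes were chosen so the full suite trains
dozens of models in minutes on one CPU. What the generator does **not**
emulate: real binding-affinity distributions, protein family structure,
correlated missingness, batch effects. Passing tests demonstrate that the
*mechanisms* behave as specified — masking, alignment, scheduling, weight
recovery — not that the model reaches any particular accuracy on real DTI
benchmarks.

## Numerical and degenerate-input choices

Attention logits are max-subtracted before exponentiation; masked members
receive exactly 0 weight (additive −1e30 bias underflows after the shift).
Confidence ranking ties break by ascending modality id. ⌈·⌉ rounds the
pacing count (floor would delay each activation by a few epochs). The
uncertainty passes reuse the training dropout rate (0.3). Task gates use
projected embeddings z̃ (the fusion space). Cosine similarity rejects zero
vectors; all-pad sequences, NaN tabular inputs, empty clusters with a
present member, and B < 2 contrastive batches raise validation errors.
Samples stripped of every modality by an evaluation drop policy receive the
neutral prediction (probability 0.5) rather than a silently restored mask.
Training aborts with a diagnostic dump on non-finite loss. All randomness
flows from `numpy` generators spawned off a single seed; two identical runs
produce byte-identical histories.

## Limitations

The autodiff engine is dense float64 and single-threaded-friendly; it is
built for the desk-scale models here (≲10⁶ parameters), not GPU-scale
training. No 3D conformers, protein structures, pretrained encoders or
memory-bank contrastive variants. The uncertainty proxy (MC-dropout
variance) measures representational stability, not task informativeness —
an uninformative but stable modality earns high confidence; identifying it
is the task gate's job. Multi-head intra-cluster attention and learned
pacing functions are out of scope.
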