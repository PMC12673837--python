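# dtifuse

Multimodal drug–target interaction (DTI) prediction with hierarchical masked
attention fusion and curriculum-guided modality optimization.

## The problem

Whether a small molecule binds a protein is rarely decidable from a single
data view. A compound comes with a molecular graph and a SMILES string; a
target with an amino-acid sequence; the biological context with
transcriptomic profiles, bioassay readouts and curated text. Real screening
data is also *incomplete*: any given drug–target pair may be missing some of
these modalities, and the ones present differ in reliability. `dtifuse`
implements a trainable pipeline that fuses K heterogeneous modalities into
one prediction while staying robust to missing and noisy inputs — for
computational chemists and ML researchers who want the mechanism itself
(attention masking, contrastive alignment, uncertainty-driven curricula)
exercisable end-to-end on a laptop, without external datasets.

## The model

**Unified multimodal encoder.** Each modality k has a dedicated encoder
φ_k — an edge-aware message-passing network for graphs
(h_v ← ReLU(W₁h_v + Σ_{u∈N(v)} ψ(h_u, e_uv)) with a permutation-invariant
READOUT), a small self-attention encoder with CLS + masked max-pooling for
SMILES/protein sequences, a ReLU layer for tabular profiles — followed by an
affine projection π_k into a shared d-dimensional space (z̃_k = π_k(z_k)).
Modalities are grouped into semantic clusters; within each cluster an
availability-masked softmax attention

  α_k = δ_k·exp(q_jᵀz̃_k) / Σ_{k′} δ_{k′}·exp(q_jᵀz̃_{k′})

fuses the present members (δ_k ∈ {0,1} is the availability mask), and a
global self-attention stage over cluster vectors — with a learned CLS slot
and no positional encoding, hence cluster-order invariant — produces the
fused representation. A symmetric InfoNCE loss over cosine similarities
aligns the modalities of the same sample against in-batch negatives, and
Bernoulli modality dropout during training simulates missing data.

**Curriculum-guided optimization.** Per modality, S stochastic (Monte-Carlo
dropout) encoder passes give an uncertainty u_k = (1/S)Σ_s‖φ^{ω_s}(x_k) − z̄_k‖²
and a confidence c_k = exp(−γu_k). A sigmoid pacing function
P(t) = K/(1+exp(−η(t−t₀))) schedules how many modalities are active at epoch
t, admitted in descending-confidence order, each ramping in through a linear
fading coefficient β_k. A task-conditioned gate r_k = σ(z̃_kᵀT_k) (with an L2
penalty on T) modulates relevance per sample. The final fusion weights
compose all of it:

  α̃_k ∝ δ′_k · β_k(t) · c_k · r_k   (normalized over the active set).

## Worked example

```python
from dtifuse import SynthSpec, TrainConfig, evaluate, generate, train

spec = SynthSpec(
    n_samples=1000,
    modalities=("transcriptomics", "bioassay", "text_embedding"),
    informative=(1, 1, 0),          # text_embedding is pure noise
    effect_size=2.0, missing_rate=(0.1, 0.1, 0.1), seed=11,
)
manifest, samples, _ = generate(spec)
cfg = TrainConfig(seed=11, max_epochs=25)
cfg.model.fusion_mode = "acmo_flat"
trained = train(manifest, samples, cfg)
rep = evaluate(trained, samples, split="test")
print(rep.auc, rep.mean_modality_weights)
```

Running `python examples/train_and_evaluate.py` (this exact setup) prints:

```
trained 25 epochs, final val loss 2.3696

held-out AUC: 0.944  accuracy: 0.850
mean fusion weights (noise modality should be smallest):
  transcriptomics  0.321
  bioassay         0.375
  text_embedding   0.304

AUC without the noise modality: 0.935 (shift 0.008, should be small)
AUC with only the noise modality: 0.493 (should be near 0.5 — no signal left)
```

(The validation loss shown includes the contrastive alignment term, which is
nonzero by design once several modalities are active; early stopping tracks
the task component.)

The model recovers the planted signal (AUC well above chance), assigns the
pure-noise modality the smallest fusion weight, barely changes when that
modality is removed at test time, and collapses to chance when the
informative modalities are removed — the robustness profile the architecture
is built for.

Other narrative scripts live in `examples/` (dataset simulation, the
curriculum schedule, uncertainty-driven downweighting, and a full
`dtifuse simulate/train/evaluate/predict/inspect-attention` shell pipeline).

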