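"""Monte-Carlo-dropout uncertainty turns noise into fusion downweighting.

Degrade one tabular modality with strong additive noise; the stochastic
encoder's pass-to-pass variance rises for it, its confidence exp(-gamma*u)
falls, and the composed fusion weight drops below the clean modality's.
"""

import numpy as np

from dtifuse import SynthSpec, UncertaintyConfig, compose_weights, confidence, degrade, generate
from dtifuse.acmo import estimate_uncertainty
from dtifuse.encoders import EncoderConfig, TabularEncoder

spec = SynthSpec(n_samples=300, modalities=("transcriptomics", "bioassay"),
                 informative=(1, 1), seed=8)
_, samples, _ = generate(spec)
noisy = degrade(samples, "bioassay", added_noise=2.0, seed=9)

enc = TabularEncoder(16, EncoderConfig(tabular_latent=32, dropout_rate=0.3),
                     np.random.default_rng(10))
ucfg = UncertaintyConfig(n_passes=8)

u = {}
for name in ("transcriptomics", "bioassay"):
    X = np.stack([s.payloads[name] for s in noisy])
    _, u_rows = estimate_uncertainty(lambda x, r: enc(x, rng=r), X, ucfg,
                                     np.random.default_rng(11))
    u[name] = float(u_rows.mean())
    print(f"{name:16s} mean MC variance u = {u[name]:.2f}")

u_vec = np.array([u["transcriptomics"], u["bioassay"]])
c = confidence(u_vec / u_vec.mean())          # scale-normalized, gamma = 1
alpha, _ = compose_weights([1, 1], [1, 1], c, [0.5, 0.5], [True, True])
print(f"\nconfidences: clean={c[0]:.3f}, degraded={c[1]:.3f}")
print(f"composed fusion weights: clean={alpha[0, 0]:.3f}, "
      f"degraded={alpha[0, 1]:.3f}  (degraded modality downweighted)")
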