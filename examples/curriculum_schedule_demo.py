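"""Watch the curriculum schedule unfold with frozen confidences.

Three modalities with reliabilities 0.9 > 0.6 > 0.3: the sigmoid pacing
function P(t) = K/(1+exp(-eta(t-t0))) admits them one at a time in descending
confidence order, and each newly admitted modality ramps in linearly over the
fading window.
"""

import numpy as np

from dtifuse import CurriculumConfig, CurriculumState, update_schedule

c = np.array([0.9, 0.6, 0.3])
cfg = CurriculumConfig(steepness=1.0, midpoint=10, fade_window=5)
state = CurriculumState(K=3)

print("t   active        beta")
for t in range(0, 21):
    state = update_schedule(state, c, t=t, config=cfg)
    active = "".join("x" if a else "." for a in state.active)
    beta = " ".join(f"{b:.1f}" for b in state.beta)
    print(f"{t:<3d} {active:12s}  {beta}")

print("\nactivation times:", state.activation_time.tolist(),
      "(ordered by confidence: most reliable first)")
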