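import os

# single-threaded BLAS: the matrices here are small, thread fan-out only adds
# overhead and run-to-run jitter
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
           "NUMEXPR_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from dtifuse.synthetic import SynthSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tabular_trio():
    """Small all-tabular dataset: two informative modalities, one noise."""
    spec = SynthSpec(
        n_samples=120,
        modalities=("transcriptomics", "bioassay", "text_embedding"),
        informative=(1, 1, 0),
        effect_size=2.0,
        missing_rate=(0.1, 0.1, 0.1),
        seed=21,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def mixed_modalities():
    """Graph + protein sequence + transcriptomics, complete availability."""
    spec = SynthSpec(n_samples=24, K=3, informative=(1, 0, 1), seed=5)
    return generate(spec)
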