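"""Synthetic multimodal datasets with a planted, tunable label signal.

The generator emulates the structure of multimodal drug–target interaction
data — K = 3–5 modalities, per-modality noise scales, Bernoulli missingness —
with a planted signal simple enough that recovery is analyzable:

* informative tabular modalities are linear-Gaussian: ``y·effect_size·w_k``
  along a fixed random unit direction ``w_k`` plus isotropic noise;
* an informative graph modality is an Erdős–Rényi graph whose mean node
  feature is shifted by ``y·effect_size`` along a fixed direction;
* an informative sequence modality draws its letters from one of two
  distributions depending on the label;
* non-informative modalities are pure noise of the same shape.

Samples where every modality would be missing are re-drawn, so each sample
has at least one available modality by construction.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    MODALITY_FAMILIES,
    DatasetManifest,
    ModalityKind,
    MolecularGraph,
    MultimodalSample,
    ValidationError,
)
from .io import write_dataset

__all__ = ["SynthSpec", "generate", "degrade", "make_fixture", "FIXTURES"]

_AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

_DEFAULT_MODALITIES = {
    3: ("graph", "protein_seq", "transcriptomics"),
    4: ("graph", "protein_seq", "transcriptomics", "bioassay"),
    5: ("graph", "protein_seq", "transcriptomics", "bioassay", "text_embedding"),
}


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 2000
    modalities: tuple[str, ...] = ()          # defaults to the K-modality set
    K: int = 3
    informative: tuple[int, ...] = ()         # 1 = carries label signal
    noise_scale: tuple[float, ...] = ()       # σ_k, default 1.0 each
    missing_rate: tuple[float, ...] = ()      # ρ_k, default 0.0 each
    task: str = "binary"
    effect_size: float = 2.0
    seed: int = 0
    tabular_dim: int = 16
    graph_feature_dim: int = 8
    graph_nodes: tuple[int, int] = (8, 16)
    graph_edge_prob: float = 0.3
    #: label shift of the edge probability for an informative graph modality
    #: (0 = signal only in the node-feature mean); structure that survives no
    #: amount of node-feature pooling, so graph encoders are genuinely needed
    graph_structure_shift: float = 0.0
    seq_length: tuple[int, int] = (20, 40)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        if not self.modalities:
            if self.K not in _DEFAULT_MODALITIES:
                raise ValidationError("K must be in 3..5 when modalities not given")
            self.modalities = _DEFAULT_MODALITIES[self.K]
        self.K = len(self.modalities)
        for m in self.modalities:
            if m not in MODALITY_FAMILIES:
                raise ValidationError(f"unknown modality {m!r}")
        if not self.informative:
            self.informative = (1,) + (0,) * (self.K - 1)
        if not self.noise_scale:
            self.noise_scale = (1.0,) * self.K
        if not self.missing_rate:
            self.missing_rate = (0.0,) * self.K
        for t in (self.informative, self.noise_scale, self.missing_rate):
            if len(t) != self.K:
                raise ValidationError("per-modality tuples must have length K")
        if not any(self.informative):
            raise ValidationError("at least one modality must be informative")
        if any(not (0.0 <= r < 1.0) for r in self.missing_rate):
            raise ValidationError("missing rates must satisfy 0 <= rho < 1")
        if any(s < 0 for s in self.noise_scale):
            raise ValidationError("noise scales must be non-negative")
        if self.task not in ("binary", "regression"):
            raise ValidationError(f"unknown task {self.task!r}")


def generate(spec: SynthSpec) -> tuple[DatasetManifest, list[MultimodalSample], dict]:
    """Draw a dataset under ``spec``; returns (manifest, samples, ground_truth)."""
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_samples, spec.K

    if spec.task == "binary":
        y = rng.binomial(1, 0.5, size=n).astype(np.float64)
    else:
        y = rng.standard_normal(n)

    # fixed random signal directions, one per modality
    directions: dict[str, np.ndarray] = {}
    seq_logits: dict[str, np.ndarray] = {}
    for name in spec.modalities:
        fam = MODALITY_FAMILIES[name]
        if fam == "tabular":
            w = rng.standard_normal(spec.tabular_dim)
            directions[name] = w / np.linalg.norm(w)
        elif name == "graph":
            w = rng.standard_normal(spec.graph_feature_dim)
            directions[name] = w / np.linalg.norm(w)
        else:  # sequential
            seq_logits[name] = rng.standard_normal(len(_AMINO_ACIDS))

    # availability: Bernoulli(1 - rho), all-zero rows re-drawn
    rho = np.array(spec.missing_rate)
    delta = rng.binomial(1, 1.0 - rho, size=(n, K))
    bad = ~delta.any(axis=1)
    while bad.any():
        delta[bad] = rng.binomial(1, 1.0 - rho, size=(bad.sum(), K))
        bad = ~delta.any(axis=1)

    samples: list[MultimodalSample] = []
    splits = _assign_splits(n, spec.split_fractions)
    for i in range(n):
        s = MultimodalSample(sample_id=f"s{i:05d}", label=float(y[i]), split=splits[i])
        for k, name in enumerate(spec.modalities):
            s.availability[name] = int(delta[i, k])
            if not delta[i, k]:
                continue
            signal = y[i] * spec.effect_size if spec.informative[k] else 0.0
            s.payloads[name] = _draw_payload(name, spec, signal, spec.noise_scale[k],
                                             directions, seq_logits, rng)
        samples.append(s)

    manifest = DatasetManifest(
        name=f"synthetic_seed{spec.seed}",
        task=spec.task,
        modalities=ModalityKind.declare(list(spec.modalities)),
        sources={m: {} for m in spec.modalities},
        tabular_dims={m: spec.tabular_dim for m in spec.modalities
                      if MODALITY_FAMILIES[m] == "tabular"},
    )
    truth = {
        "spec": dataclasses.asdict(spec),
        "y": y.tolist(),
        "delta": delta.tolist(),
        "directions": {k: v.tolist() for k, v in directions.items()},
        "seq_logits": {k: v.tolist() for k, v in seq_logits.items()},
    }
    return manifest, samples, truth


def _assign_splits(n: int, fractions: tuple[float, float, float]) -> list[str]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)


def _draw_payload(name, spec: SynthSpec, signal: float, sigma: float,
                  directions, seq_logits, rng: np.random.Generator):
    fam = MODALITY_FAMILIES[name]
    if fam == "tabular":
        return signal * directions[name] + sigma * rng.standard_normal(spec.tabular_dim)
    if name == "graph":
        m = int(rng.integers(spec.graph_nodes[0], spec.graph_nodes[1] + 1))
        nodes = signal * directions[name] + sigma * rng.standard_normal(
            (m, spec.graph_feature_dim))
        p_edge = spec.graph_edge_prob
        if signal != 0.0 and spec.graph_structure_shift:
            p_edge = float(np.clip(
                p_edge + np.sign(signal) * spec.graph_structure_shift, 0.05, 0.95))
        iu, ju = np.triu_indices(m, k=1)
        keep = rng.random(iu.shape[0]) < p_edge
        edge_list = np.stack([iu[keep], ju[keep]], axis=1)
        bond = rng.integers(0, 4, size=edge_list.shape[0])
        edge_features = np.eye(4)[bond] if edge_list.size else np.zeros((0, 4))
        return MolecularGraph(nodes, edge_list, edge_features)
    # sequential: letters from a label-tilted categorical distribution
    logits = signal * seq_logits[name] * 0.5
    p = np.exp(logits - logits.max())
    p /= p.sum()
    length = int(rng.integers(spec.seq_length[0], spec.seq_length[1] + 1))
    letters = rng.choice(len(_AMINO_ACIDS), size=length, p=p)
    return "".join(_AMINO_ACIDS[a] for a in letters)


def degrade(samples: list[MultimodalSample], modality: str, added_noise: float,
            seed: int = 0) -> list[MultimodalSample]:
    """Return a copy with N(0, added_noise²) added to one vector-valued
    modality; every other payload is bit-identical."""
    if added_noise < 0:
        raise ValidationError("added_noise must be non-negative")
    names = {n for s in samples for n in s.availability}
    if modality not in names:
        raise ValidationError(f"modality {modality!r} not present; have {sorted(names)}")
    if MODALITY_FAMILIES.get(modality) != "tabular":
        raise ValidationError(f"degrade only applies to tabular/embedding modalities, "
                              f"not {modality!r}")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        c = copy.deepcopy(s)
        if c.availability.get(modality) and added_noise > 0:
            vec = c.payloads[modality]
            c.payloads[modality] = vec + added_noise * rng.standard_normal(vec.shape)
        out.append(c)
    return out


#: fixture name -> spec + optional degradation, all with fixed internal seeds
FIXTURES = {
    "tiny_complete": dict(
        spec=SynthSpec(n_samples=20, K=3, informative=(1, 0, 1), seed=7),
    ),
    "tiny_missing": dict(
        spec=SynthSpec(n_samples=20, K=3, informative=(1, 0, 1),
                       missing_rate=(0.0, 0.3, 0.3), seed=8),
    ),
    "noisy_modality": dict(
        spec=SynthSpec(n_samples=30,
                       modalities=("transcriptomics", "bioassay", "text_embedding"),
                       informative=(1, 1, 0), seed=9),
        degrade=("bioassay", 2.0),
    ),
}


def make_fixture(name: str, outdir: str | Path) -> Path:
    """Write a small registered dataset to ``outdir``; deterministic across
    runs (fixed internal seeds).  Returns the manifest path."""
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; registry: {sorted(FIXTURES)}")
    entry = FIXTURES[name]
    manifest, samples, truth = generate(entry["spec"])
    if "degrade" in entry:
        mod, noise = entry["degrade"]
        samples = degrade(samples, mod, noise, seed=entry["spec"].seed + 1)
    manifest.name = name
    outdir = Path(outdir)
    mpath = write_dataset(manifest, samples, outdir)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return mpath
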