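"""Core data model for multimodal drug–target interaction samples.

A dataset declares an ordered set of modalities (molecular graph, SMILES,
protein sequence, transcriptomics, bioassay profile, precomputed text
embedding).  Each sample carries one payload per *available* modality plus a
binary availability mask δ — the single source of truth for missingness that
the masked fusion stage consumes downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MODALITY_FAMILIES",
    "ModalityKind",
    "MolecularGraph",
    "Vocab",
    "TokenSequence",
    "MultimodalSample",
    "DatasetManifest",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


#: modality name -> encoder family
MODALITY_FAMILIES = {
    "graph": "structural",
    "smiles": "sequential",
    "protein_seq": "sequential",
    "transcriptomics": "tabular",
    "bioassay": "tabular",
    "text_embedding": "tabular",
}


@dataclass(frozen=True)
class ModalityKind:
    """One declared modality: 1-based contiguous id, name, encoder family."""

    id: int
    name: str
    family: str = ""

    def __post_init__(self):
        if self.name not in MODALITY_FAMILIES:
            raise ValidationError(
                f"unknown modality name {self.name!r}; expected one of "
                f"{sorted(MODALITY_FAMILIES)}"
            )
        if not self.family:
            object.__setattr__(self, "family", MODALITY_FAMILIES[self.name])

    @staticmethod
    def declare(names: list[str]) -> list["ModalityKind"]:
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate modality names in {names}")
        return [ModalityKind(i + 1, n) for i, n in enumerate(names)]


@dataclass
class MolecularGraph:
    """Undirected molecular graph: per-atom features, bond list, bond features.

    Edges are stored once; encoders expand them to both directions.
    """

    node_features: np.ndarray  # (|V|, d_v)
    edge_list: np.ndarray      # (|E|, 2) int
    edge_features: np.ndarray  # (|E|, d_e)

    def __post_init__(self):
        self.node_features = np.atleast_2d(np.asarray(self.node_features, dtype=np.float64))
        self.edge_list = np.asarray(self.edge_list, dtype=np.int64).reshape(-1, 2)
        ef = np.asarray(self.edge_features, dtype=np.float64)
        self.edge_features = (ef.reshape(self.edge_list.shape[0], -1)
                              if ef.size else ef.reshape(0, ef.shape[-1] if ef.ndim > 1 else 1))
        n = self.node_features.shape[0]
        if n < 1:
            raise ValidationError("graph must have at least one node")
        if self.edge_list.size:
            if self.edge_list.min() < 0 or self.edge_list.max() >= n:
                raise ValidationError("edge endpoint out of range")
            if (self.edge_list[:, 0] == self.edge_list[:, 1]).any():
                raise ValidationError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_list.shape[0]


# Atom-wise SMILES tokenization: bracket atoms, two-letter elements, ring-bond
# digits and stereo/bond symbols each become a single token.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[BCNOSPFIbcnosp]|[=#\\/@+\-\(\)\.~\*:]|\d)"
)

PAD, CLS, UNK = "<pad>", "<cls>", "<unk>"


class Vocab:
    """Token → id map with reserved PAD=0, CLS=1, UNK=2 slots."""

    def __init__(self, tokens: list[str] | None = None):
        self.token_to_id: dict[str, int] = {PAD: 0, CLS: 1, UNK: 2}
        for t in tokens or []:
            self.add(t)

    def add(self, token: str) -> int:
        return self.token_to_id.setdefault(token, len(self.token_to_id))

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK])

    @classmethod
    def fit(cls, strings: list[str], kind_name: str) -> "Vocab":
        """Build a vocabulary from (training-split) strings."""
        v = cls()
        for s in strings:
            for t in split_tokens(s, kind_name):
                v.add(t)
        return v

    def to_dict(self) -> dict[str, int]:
        return dict(self.token_to_id)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Vocab":
        v = cls()
        for t, i in sorted(d.items(), key=lambda kv: kv[1]):
            if t not in v.token_to_id:
                if v.add(t) != i:
                    raise ValidationError("non-contiguous vocabulary ids")
        return v


def split_tokens(s: str, kind_name: str) -> list[str]:
    """Split a raw string into tokens: atom-wise regex for SMILES, one token
    per amino-acid letter for protein sequences."""
    if kind_name == "smiles":
        return SMILES_TOKEN_RE.findall(s)
    return list(s)


@dataclass
class TokenSequence:
    token_ids: np.ndarray  # (L,) int, position 0 is CLS, padding only at tail
    vocab: Vocab
    max_len: int

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        if self.token_ids.shape[0] > self.max_len:
            raise ValidationError("token sequence longer than max_len")
        if self.token_ids.shape[0] == 0 or self.token_ids[0] != self.vocab[CLS]:
            raise ValidationError("position 0 must be the CLS token")

    @property
    def length(self) -> int:
        """Number of non-pad positions (CLS included)."""
        return int((self.token_ids != 0).sum())


@dataclass
class MultimodalSample:
    """One drug–target instance: payloads keyed by modality name, availability
    mask δ (``availability[name] == 1`` iff a payload is present), label."""

    sample_id: str
    payloads: dict[str, Any] = field(default_factory=dict)
    availability: dict[str, int] = field(default_factory=dict)
    label: float | None = None
    task_id: str = "default"
    split: str = "train"

    def validate(self, modality_names: list[str]) -> None:
        for name in modality_names:
            delta = self.availability.get(name, 0)
            present = name in self.payloads and self.payloads[name] is not None
            if bool(delta) != present:
                raise ValidationError(
                    f"sample {self.sample_id!r}: availability[{name}]={delta} "
                    f"inconsistent with payload presence"
                )
        if not any(self.availability.get(n, 0) for n in modality_names):
            raise ValidationError(
                f"sample {self.sample_id!r} has zero available modalities"
            )

    def delta_vector(self, modality_names: list[str]) -> np.ndarray:
        return np.array([self.availability.get(n, 0) for n in modality_names],
                        dtype=np.int64)


@dataclass
class DatasetManifest:
    """Binds modality declarations to source files and samples to splits."""

    name: str
    task: str  # {"binary", "regression"}
    modalities: list[ModalityKind]
    sources: dict[str, dict]  # modality name -> {"file": ..., "column": ...}
    tabular_dims: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in ("binary", "regression"):
            raise ValidationError(f"unknown task type {self.task!r}")
        ids = [m.id for m in self.modalities]
        if ids != list(range(1, len(ids) + 1)):
            raise ValidationError("modality ids must be contiguous from 1")

    @property
    def modality_names(self) -> list[str]:
        return [m.name for m in self.modalities]
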