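"""Readers and writers for the on-disk formats the package touches.

A dataset on disk is a manifest (YAML or JSON) plus one file per modality:

* protein sequences — FASTA, record id == sample_id (Biopython);
* SMILES — a ``.smi`` file (``SMILES<space>sample_id`` per line) or a CSV
  column;
* tabular modalities (transcriptomics, bioassay, text embeddings) — CSV with a
  header row, first column ``sample_id``;
* molecular graphs — either derived from the SMILES source with RDKit, or a
  node-table / edge-table CSV pair;
* a samples CSV assigning label, split and task id per sample.

Missingness is encoded by absence: an absent FASTA record, an absent or
NA-containing CSV row, an unparsable SMILES — all set the availability bit
δ=0 for that modality (with a logged warning), never abort the load.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .datamodel import (
    CLS,
    DatasetManifest,
    ModalityKind,
    MolecularGraph,
    MultimodalSample,
    TokenSequence,
    ValidationError,
    Vocab,
    split_tokens,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_manifest",
    "write_dataset",
    "smiles_to_graph",
    "SmilesParseError",
    "tokenize",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]


# ---------------------------------------------------------------------------
# SMILES -> molecular graph featurization (fixed, versioned recipe)
# ---------------------------------------------------------------------------

_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]  # + "other" slot
_MAX_DEGREE = 5
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1  # element+degree+aromatic
_BOND_ORDERS = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
BOND_FEATURE_DIM = len(_BOND_ORDERS)
GRAPH_FEATURIZATION_VERSION = 1


class SmilesParseError(ValidationError):
    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`.

    Node features: element one-hot over {C,N,O,S,P,F,Cl,Br,I,other} +
    degree one-hot (0..5) + aromaticity flag.  Edge features: bond-order
    one-hot {single, double, triple, aromatic}; undirected edges stored once.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    nodes = np.zeros((n, ATOM_FEATURE_DIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        e = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
        nodes[i, e] = 1.0
        deg = min(atom.GetDegree(), _MAX_DEGREE)
        nodes[i, len(_ELEMENTS) + 1 + deg] = 1.0
        nodes[i, -1] = float(atom.GetIsAromatic())
    edges, efeats = [], []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        f = np.zeros(BOND_FEATURE_DIM)
        name = str(bond.GetBondType())
        if name in _BOND_ORDERS:
            f[_BOND_ORDERS.index(name)] = 1.0
        efeats.append(f)
    edge_list = np.array(edges, dtype=np.int64).reshape(-1, 2)
    edge_features = np.array(efeats, dtype=np.float64).reshape(-1, BOND_FEATURE_DIM)
    return MolecularGraph(nodes, edge_list, edge_features)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize(seq: str, kind: ModalityKind | str, vocab: Vocab,
             max_len: int = 256) -> TokenSequence:
    """Tokenize a SMILES or protein string; CLS prepended, tail-truncated.

    Unknown symbols map to UNK.  The vocabulary must have been fit on the
    training split only.
    """
    if not seq:
        raise ValidationError("cannot tokenize an empty string")
    kind_name = kind if isinstance(kind, str) else kind.name
    toks = split_tokens(seq, kind_name)
    ids = [vocab[CLS]] + [vocab[t] for t in toks]
    ids = ids[:max_len]
    return TokenSequence(np.array(ids, dtype=np.int64), vocab, max_len)


# ---------------------------------------------------------------------------
# Manifest reading
# ---------------------------------------------------------------------------

def _load_manifest_dict(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"referenced file does not exist: {path}")
    return path


def read_manifest(path: str | Path) -> tuple[DatasetManifest, list[MultimodalSample]]:
    """Load a dataset: manifest + per-modality files -> samples in manifest order.

    δ is inferred from presence: an empty/NA tabular cell, a missing FASTA
    record or an unparsable SMILES sets δ=0 for that modality.
    """
    path = Path(path)
    raw = _load_manifest_dict(_require(path))
    base = path.parent

    names = [m["name"] for m in raw["modalities"]]
    manifest = DatasetManifest(
        name=raw.get("name", path.stem),
        task=raw.get("task", "binary"),
        modalities=ModalityKind.declare(names),
        sources={m["name"]: {k: v for k, v in m.items() if k != "name"}
                 for m in raw["modalities"]},
    )

    samples_df = pd.read_csv(_require(base / raw["samples_file"]), dtype={"sample_id": str})
    ids = samples_df["sample_id"].tolist()
    dup = samples_df["sample_id"][samples_df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate sample_id {dup.iloc[0]!r} in samples file")

    samples = {
        sid: MultimodalSample(
            sample_id=sid,
            label=None if pd.isna(row.get("label")) else float(row["label"]),
            split=str(row.get("split", "train")),
            task_id=str(row.get("task_id", "default")),
        )
        for sid, (_, row) in zip(ids, samples_df.iterrows())
    }

    for name in names:
        src = manifest.sources[name]
        payloads = _read_modality(name, src, base, ids)
        for sid in ids:
            p = payloads.get(sid)
            samples[sid].payloads[name] = p
            samples[sid].availability[name] = int(p is not None)
        dims = {p.shape[0] for p in payloads.values()
                if isinstance(p, np.ndarray) and p.ndim == 1}
        if len(dims) > 1:
            raise ValidationError(f"inconsistent feature dimension in modality {name!r}")
        if dims:
            manifest.tabular_dims[name] = dims.pop()
            declared = src.get("dim")
            if declared is not None and int(declared) != manifest.tabular_dims[name]:
                raise ValidationError(
                    f"modality {name!r}: declared dim {declared} != "
                    f"loaded dim {manifest.tabular_dims[name]}"
                )

    out = [samples[sid] for sid in ids]
    for s in out:
        s.payloads = {k: v for k, v in s.payloads.items() if v is not None}
        s.validate(names)
    return manifest, out


def _read_modality(name: str, src: dict, base: Path, ids: list[str]) -> dict:
    file = _require(base / src["file"])
    if name == "protein_seq" or src.get("format") == "fasta":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(file), "fasta")}
        return {sid: records[sid] for sid in ids if sid in records and records[sid]}
    if name == "smiles":
        return _read_smiles(file, src, ids)
    if name == "graph":
        if src.get("from_smiles"):
            return _graphs_from_smiles(_read_smiles(file, src, ids))
        edges_file = _require(base / src["edges_file"])
        return _read_graph_tables(file, edges_file, ids)
    # tabular
    df = pd.read_csv(file, dtype={"sample_id": str}).set_index("sample_id")
    out = {}
    for sid in ids:
        if sid not in df.index:
            continue
        row = df.loc[sid].to_numpy(dtype=np.float64)
        if np.isnan(row).any():
            logger.warning("sample %s: NA in modality %s -> marked missing", sid, name)
            continue
        out[sid] = row
    return out


def _read_smiles(file: Path, src: dict, ids: list[str]) -> dict[str, str]:
    if file.suffix == ".smi":
        out = {}
        for line in file.read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                out[parts[1]] = parts[0]
        return {sid: out[sid] for sid in ids if sid in out and out[sid]}
    df = pd.read_csv(file, dtype=str).set_index("sample_id")
    col = src.get("column", "smiles")
    return {sid: df.loc[sid, col] for sid in ids
            if sid in df.index and isinstance(df.loc[sid, col], str) and df.loc[sid, col]}


def _graphs_from_smiles(smiles: dict[str, str]) -> dict[str, MolecularGraph]:
    out = {}
    for sid, smi in smiles.items():
        try:
            out[sid] = smiles_to_graph(smi)
        except SmilesParseError:
            logger.warning("sample %s: unparsable SMILES -> graph marked missing", sid)
    return out


def _read_graph_tables(nodes_file: Path, edges_file: Path,
                       ids: list[str]) -> dict[str, MolecularGraph]:
    nodes = pd.read_csv(nodes_file, dtype={"sample_id": str})
    edges = pd.read_csv(edges_file, dtype={"sample_id": str})
    nfeat_cols = [c for c in nodes.columns if c.startswith("f")]
    efeat_cols = [c for c in edges.columns if c.startswith("e")]
    out = {}
    for sid, grp in nodes.groupby("sample_id", sort=False):
        grp = grp.sort_values("node_idx")
        eg = edges[edges["sample_id"] == sid]
        out[sid] = MolecularGraph(
            grp[nfeat_cols].to_numpy(np.float64),
            eg[["src", "dst"]].to_numpy(np.int64) if len(eg) else np.zeros((0, 2), np.int64),
            eg[efeat_cols].to_numpy(np.float64) if len(eg) else np.zeros((0, len(efeat_cols))),
        )
    return {sid: out[sid] for sid in ids if sid in out}


# ---------------------------------------------------------------------------
# Dataset writing (round-trip counterpart of read_manifest)
# ---------------------------------------------------------------------------

def write_dataset(manifest: DatasetManifest, samples: list[MultimodalSample],
                  outdir: str | Path) -> Path:
    """Write manifest + modality files so that :func:`read_manifest` restores
    sample ids, δ masks and labels exactly.  Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = [{"sample_id": s.sample_id, "label": s.label, "split": s.split,
             "task_id": s.task_id} for s in samples]
    pd.DataFrame(rows).to_csv(outdir / "samples.csv", index=False)

    mod_entries = []
    for kind in manifest.modalities:
        name = kind.name
        entry: dict = {"name": name}
        if name == "protein_seq":
            entry["file"] = "proteins.fasta"
            with open(outdir / entry["file"], "w") as fh:
                for s in samples:
                    if s.availability.get(name):
                        fh.write(f">{s.sample_id}\n{s.payloads[name]}\n")
        elif name == "smiles":
            entry["file"] = "drugs.smi"
            with open(outdir / entry["file"], "w") as fh:
                for s in samples:
                    if s.availability.get(name):
                        fh.write(f"{s.payloads[name]} {s.sample_id}\n")
        elif name == "graph":
            entry["file"], entry["edges_file"] = "graph_nodes.csv", "graph_edges.csv"
            nrows, erows = [], []
            for s in samples:
                if not s.availability.get(name):
                    continue
                g: MolecularGraph = s.payloads[name]
                for i in range(g.n_nodes):
                    nrows.append({"sample_id": s.sample_id, "node_idx": i,
                                  **{f"f{j}": g.node_features[i, j]
                                     for j in range(g.node_features.shape[1])}})
                for i in range(g.n_edges):
                    erows.append({"sample_id": s.sample_id,
                                  "src": g.edge_list[i, 0], "dst": g.edge_list[i, 1],
                                  **{f"e{j}": g.edge_features[i, j]
                                     for j in range(g.edge_features.shape[1])}})
            pd.DataFrame(nrows).to_csv(outdir / entry["file"], index=False)
            ecols = ["sample_id", "src", "dst"] + [f"e{j}" for j in
                                                   range(_edge_dim(samples, name))]
            edf = pd.DataFrame(erows) if erows else pd.DataFrame(columns=ecols)
            edf.to_csv(outdir / entry["edges_file"], index=False)
        else:  # tabular
            entry["file"] = f"{name}.csv"
            rows = []
            for s in samples:
                if s.availability.get(name):
                    vec = s.payloads[name]
                    rows.append({"sample_id": s.sample_id,
                                 **{f"x{j}": vec[j] for j in range(vec.shape[0])}})
            pd.DataFrame(rows).to_csv(outdir / entry["file"], index=False)
        mod_entries.append(entry)

    doc = {"name": manifest.name, "task": manifest.task,
           "modalities": mod_entries, "samples_file": "samples.csv"}
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(doc, sort_keys=False))
    return mpath


def _edge_dim(samples: list[MultimodalSample], name: str) -> int:
    for s in samples:
        if s.availability.get(name):
            return s.payloads[name].edge_features.shape[1]
    return 0
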