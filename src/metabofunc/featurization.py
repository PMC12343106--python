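"""Molecular featurization: graphs, coordinates, fingerprints.

Each metabolite becomes a graph with one node per heavy atom and one edge
per bond (stored in both directions).  Node features are the one-hot element
identity over the dataset vocabulary (the N x M block A, one nonzero per
row) optionally extended with two standardized 2D-coordinate columns
(N x (M+2)); edge features one-hot the bond type over
{single, double, triple, aromatic}.  The baseline representation is a
1024-bit Morgan (circular) fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .datatypes import MetaboliteRecord
from .ingest import computed_2d_coords

logger = logging.getLogger(__name__)

__all__ = [
    "AtomVocabulary",
    "CoordinateScaler",
    "MoleculeGraph",
    "GraphBatch",
    "BOND_TYPES",
    "build_vocabulary",
    "molecule_to_graph",
    "normalize_molecule_coords",
    "circular_fingerprint",
    "batch_graphs",
]

BOND_TYPES = ("single", "double", "triple", "aromatic")
_BOND_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

_PERIODIC = Chem.GetPeriodicTable()


@dataclass
class AtomVocabulary:
    """Ordered element vocabulary defining the one-hot columns of A."""

    elements: list[str]
    include_unknown: bool = True

    def __post_init__(self):
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate elements in vocabulary")

    @property
    def size(self) -> int:
        return len(self.elements) + (1 if self.include_unknown else 0)

    def index(self, symbol: str, mol_id: str = "?") -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            if self.include_unknown:
                return len(self.elements)
            raise ValueError(
                f"element {symbol!r} of molecule {mol_id} not in vocabulary "
                f"{self.elements} (unknown slot disabled)"
            ) from None

    def to_json_dict(self) -> dict:
        return {"elements": self.elements, "include_unknown": self.include_unknown}

    @classmethod
    def from_json_dict(cls, d: dict) -> "AtomVocabulary":
        return cls(list(d["elements"]), bool(d["include_unknown"]))


def build_vocabulary(records: list[MetaboliteRecord], include_unknown: bool = True
                     ) -> tuple[AtomVocabulary, list[str]]:
    """Union of element symbols over all parseable molecules, by atomic number.

    Returns the vocabulary and the ids of molecules whose SMILES failed to
    parse (excluded, reported, never silently dropped).
    """
    if not records:
        raise ValueError("no records")
    symbols: set[str] = set()
    failed: list[str] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            failed.append(rec.metabolite_id)
            continue
        symbols.update(a.GetSymbol() for a in mol.GetAtoms())
    if failed:
        logger.warning("%d unparseable SMILES excluded from vocabulary", len(failed))
    ordered = sorted(symbols, key=lambda s: _PERIODIC.GetAtomicNumber(s))
    return AtomVocabulary(ordered, include_unknown), failed


@dataclass
class CoordinateScaler:
    """Dataset-level per-axis standardization of per-molecule-normalized coords.

    Fitted exactly once on the training molecules and reused on test
    molecules to avoid leaking test geometry into the feature scale.
    """

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, normalized_coords: list[np.ndarray]) -> "CoordinateScaler":
        allc = np.concatenate([c for c in normalized_coords if len(c)], axis=0)
        self.mean = allc.mean(axis=0)
        std = allc.std(axis=0)
        if (std == 0).any():
            logger.warning("coordinate axis with zero spread; passing axis through")
            std = np.where(std == 0, 1.0, std)
        self.std = std
        return self

    def transform(self, normalized: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("CoordinateScaler not fitted")
        return (normalized - self.mean) / self.std

    def to_json_dict(self) -> dict:
        return {"mean": None if self.mean is None else self.mean.tolist(),
                "std": None if self.std is None else self.std.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "CoordinateScaler":
        sc = cls()
        if d["mean"] is not None:
            sc.mean = np.asarray(d["mean"], dtype=np.float64)
            sc.std = np.asarray(d["std"], dtype=np.float64)
        return sc


def normalize_molecule_coords(coords) -> np.ndarray:
    """Per-molecule normalization: center at the centroid, scale by max |coord|.

    Keeps raw drawing units from dominating the one-hot block; the dataset
    scaler then z-scores each axis.  Single-atom molecules map to the origin.
    """
    c = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    if len(c) == 0:
        return c
    c = c - c.mean(axis=0)
    m = np.abs(c).max()
    if m > 0:
        c = c / m
    return c


@dataclass
class MoleculeGraph:
    mol_id: str
    node_features: np.ndarray  # N x (M+2) or N x M
    edge_index: np.ndarray  # 2 x 2P, both directions of every bond
    edge_type: np.ndarray  # 2P x 4 one-hot bond type
    n_atoms: int = field(init=False)

    def __post_init__(self):
        self.n_atoms = self.node_features.shape[0]
        if self.edge_index.size and self.edge_index.max() >= self.n_atoms:
            raise ValueError("edge index out of range")

    @property
    def n_bonds(self) -> int:
        return self.edge_index.shape[1] // 2


def molecule_to_graph(
    record: MetaboliteRecord,
    vocab: AtomVocabulary,
    scaler: CoordinateScaler | None = None,
    use_coords: bool = True,
) -> MoleculeGraph:
    """Build the graph representation of one metabolite.

    Atom order is the SMILES parser's order (sum-pooled models are
    permutation invariant, verified separately).  With ``use_coords`` the
    node-feature width is M+2, without it exactly M.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.metabolite_id}")
    n = mol.GetNumAtoms()
    a = np.zeros((n, vocab.size), dtype=np.float64)
    for i, atom in enumerate(mol.GetAtoms()):
        a[i, vocab.index(atom.GetSymbol(), record.metabolite_id)] = 1.0

    if use_coords:
        coords = record.coords
        if coords is None:
            coords = computed_2d_coords(record.smiles)
        if coords is None or len(coords) != n:
            raise ValueError(f"coordinates unavailable for {record.metabolite_id}")
        if scaler is None or not scaler.fitted:
            raise ValueError("use_coords requires a fitted CoordinateScaler")
        xy = scaler.transform(normalize_molecule_coords(coords))
        node_features = np.concatenate([a, xy], axis=1)
    else:
        node_features = a

    src, dst, types = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        t = _BOND_INDEX.get(bond.GetBondType(), 0)
        src.extend((u, v))
        dst.extend((v, u))
        types.extend((t, t))
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_type = np.zeros((len(types), 4), dtype=np.float64)
    if types:
        edge_type[np.arange(len(types)), types] = 1.0
    return MoleculeGraph(record.metabolite_id, node_features, edge_index, edge_type)


def circular_fingerprint(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Morgan fingerprint bit vector; canonicalized, hence spelling-invariant."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


@dataclass
class GraphBatch:
    """Several molecule graphs packed as one disjoint-union graph."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_type: np.ndarray
    batch: np.ndarray  # node -> graph position
    mol_ids: list[str]

    @property
    def n_graphs(self) -> int:
        return len(self.mol_ids)


def batch_graphs(graphs: list[MoleculeGraph]) -> GraphBatch:
    feats, eis, ets, batch, ids = [], [], [], [], []
    offset = 0
    for g_pos, g in enumerate(graphs):
        feats.append(g.node_features)
        eis.append(g.edge_index + offset)
        ets.append(g.edge_type)
        batch.append(np.full(g.n_atoms, g_pos, dtype=np.int64))
        ids.append(g.mol_id)
        offset += g.n_atoms
    return GraphBatch(
        np.concatenate(feats, axis=0),
        np.concatenate(eis, axis=1) if eis else np.zeros((2, 0), dtype=np.int64),
        np.concatenate(ets, axis=0) if ets else np.zeros((0, 4)),
        np.concatenate(batch) if batch else np.zeros(0, dtype=np.int64),
        ids,
    )
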