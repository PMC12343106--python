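"""Core data model: metabolite records, the functional ontology, truth tables.

The package mirrors the HMDB data shape: each metabolite carries a SMILES
structure, a detection status, optional 2D depiction coordinates and a set of
functional ontology term annotations.  The ontology is a forest rooted at the
four top-level functional categories (Disposition, Role, Process,
Physiological effect); model outputs are selected leaf terms of one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

CATEGORIES = ("Disposition", "Role", "Process", "Physiological effect")


class DetectionStatus(str, Enum):
    """HMDB detection status; only detected-and-quantified metabolites are modeled."""

    expected = "expected"
    predicted = "predicted"
    detected_not_quantified = "detected_not_quantified"
    detected_quantified = "detected_quantified"

    @classmethod
    def parse(cls, raw: str) -> "DetectionStatus":
        norm = raw.strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "detected_but_not_quantified": "detected_not_quantified",
            "detected_and_quantified": "detected_quantified",
            "quantified": "detected_quantified",
        }
        norm = aliases.get(norm, norm)
        try:
            return cls(norm)
        except ValueError:
            raise ValueError(f"unknown detection status {raw!r}") from None


@dataclass
class MetaboliteRecord:
    metabolite_id: str
    smiles: str
    status: DetectionStatus
    term_ids: set[str] = field(default_factory=set)
    coords: list[tuple[float, float]] | None = None
    name: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.smiles:
            self.flags.add("missing_smiles")


@dataclass
class OntologyNode:
    term_id: str
    label: str
    parent: str | None
    category: str


class OntologyTree:
    """Term hierarchy: a forest whose roots are the four functional categories."""

    def __init__(self, nodes: dict[str, OntologyNode] | None = None):
        self.nodes: dict[str, OntologyNode] = dict(nodes or {})

    def add_node(self, term_id: str, label: str | None = None, parent: str | None = None,
                 category: str | None = None) -> None:
        if parent is not None and parent in self.nodes and category is None:
            category = self.nodes[parent].category
        if category is None:
            raise ValueError(f"cannot infer category for term {term_id!r}")
        existing = self.nodes.get(term_id)
        if existing is not None:
            if parent is not None and existing.parent is None and term_id not in CATEGORIES:
                existing.parent = parent
            return
        self.nodes[term_id] = OntologyNode(term_id, label or term_id, parent, category)

    def children(self, term_id: str) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.parent == term_id)

    def ancestors(self, term_id: str) -> list[str]:
        out = []
        cur = self.nodes[term_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def descendants(self, term_id: str) -> set[str]:
        out: set[str] = set()
        stack = [term_id]
        while stack:
            t = stack.pop()
            for c in self.children(t):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def roots(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.parent is None)

    def validate(self) -> None:
        for t, n in self.nodes.items():
            if n.parent is None:
                if t not in CATEGORIES:
                    raise ValueError(f"root {t!r} is not one of the four categories")
                continue
            if n.parent not in self.nodes:
                raise ValueError(f"term {t!r} has unknown parent {n.parent!r}")
            seen = {t}
            cur = n.parent
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through {t!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def to_json_dict(self) -> dict:
        return {
            t: {"label": n.label, "parent": n.parent, "category": n.category}
            for t, n in sorted(self.nodes.items())
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "OntologyTree":
        tree = cls()
        for t, n in d.items():
            tree.nodes[t] = OntologyNode(t, n["label"], n["parent"], n["category"])
        return tree


@dataclass
class TruthTable:
    """Binary metabolite-by-term annotation matrix x_{i,j}."""

    metabolite_ids: list[str]
    term_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.metabolite_ids), len(self.term_ids)):
            raise ValueError("truth table shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("truth table must be binary")

    @property
    def density(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0

    def column(self, term_id: str) -> np.ndarray:
        return self.values[:, self.term_ids.index(term_id)]

    def restrict_terms(self, terms: list[str]) -> "TruthTable":
        idx = [self.term_ids.index(t) for t in terms]
        return TruthTable(list(self.metabolite_ids), list(terms), self.values[:, idx])

    def restrict_rows(self, metabolite_ids: list[str]) -> "TruthTable":
        idx = [self.metabolite_ids.index(m) for m in metabolite_ids]
        return TruthTable(list(metabolite_ids), list(self.term_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.metabolite_ids, columns=self.term_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "metabolite_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=np.int8))
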