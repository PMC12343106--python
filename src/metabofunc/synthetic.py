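"""Synthetic HMDB-style datasets with known structure-to-function rules.

Molecules are built by decorating random alkyl chains with chemically
distinct motif fragments (carboxyl, sulfonamide, trifluoromethyl, nitrile,
phenyl, morpholine, phosphate, pyridyl).  A molecule carries a motif's
ontology term exactly when it contains the motif (verified by substructure
match), optionally corrupted by label noise; additional noise terms with
prevalences spanning near-zero to ~0.45 give the dispersion-based label
selection both informative and degenerate columns to work on.  Every
planted rule is recorded in a manifest, so classification performance and
attention enrichment both have verifiable ground truth.

The generator writes the same XML dialect, SDF files and TSV/JSON artifacts
the ingest module reads: one code path, no mocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .datatypes import (
    CATEGORIES,
    DetectionStatus,
    MetaboliteRecord,
    OntologyTree,
    TruthTable,
)
from .ingest import build_truth_table, write_hmdb_xml

__all__ = ["Motif", "FixtureSpec", "SyntheticDataset", "generate_dataset",
           "make_unit_fixtures", "DEFAULT_MOTIFS"]


@dataclass(frozen=True)
class Motif:
    fragment: str  # SMILES fragment attachable as a chain branch
    term_id: str
    category: str
    attach_probability: float = 0.4


# Two motif-linked leaf terms per functional category.  Fragments are
# mutually exclusive under substructure matching (e.g. pyridyl does not
# contain the phenyl pattern), so planted truths do not bleed into each other.
DEFAULT_MOTIFS = (
    Motif("C(=O)O", "t-carboxyl", "Process"),
    Motif("c1ccccc1", "t-phenyl", "Process"),
    Motif("S(=O)(=O)N", "t-sulfonamide", "Role"),
    Motif("N1CCOCC1", "t-morpholine", "Role"),
    Motif("C(F)(F)F", "t-trifluoromethyl", "Disposition"),
    Motif("OP(=O)(O)O", "t-phosphate", "Disposition"),
    Motif("C#N", "t-nitrile", "Physiological effect"),
    Motif("c1ccncc1", "t-pyridyl", "Physiological effect"),
)

_DEFAULT_STATUS_MIX = {
    DetectionStatus.detected_quantified: 0.7,
    DetectionStatus.detected_not_quantified: 0.1,
    DetectionStatus.predicted: 0.1,
    DetectionStatus.expected: 0.1,
}


@dataclass
class FixtureSpec:
    n_molecules: int = 1000
    motifs: tuple[Motif, ...] = DEFAULT_MOTIFS
    n_noise_labels: int = 40
    label_noise_rate: float = 0.05
    status_mix: dict[DetectionStatus, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATUS_MIX))
    seed: int = 0
    min_chain: int = 4
    max_chain: int = 9

    def __post_init__(self):
        for m in self.motifs:
            if not 0 <= m.attach_probability <= 1:
                raise ValueError(f"bad attach probability for {m.term_id}")
            if Chem.MolFromSmiles(m.fragment) is None:
                raise ValueError(f"invalid motif fragment {m.fragment!r}")
        if not 0 <= self.label_noise_rate <= 1:
            raise ValueError("label_noise_rate must be in [0, 1]")
        total = sum(self.status_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("status mix must sum to 1")


@dataclass
class SyntheticDataset:
    records: list[MetaboliteRecord]
    tree: OntologyTree
    manifest: dict
    spec: FixtureSpec

    @property
    def motif_term_ids(self) -> list[str]:
        return [m.term_id for m in self.spec.motifs]

    def truth_table(self, status: DetectionStatus | None = DetectionStatus.detected_quantified
                    ) -> TruthTable:
        recs = self.records if status is None else [
            r for r in self.records if r.status == status]
        return build_truth_table(recs, self.tree)

    def smiles_by_id(self) -> dict[str, str]:
        return {r.metabolite_id: r.smiles for r in self.records}


def _build_molecule(rng: np.random.Generator, fragments: list[str],
                    min_chain: int, max_chain: int) -> str | None:
    length = int(rng.integers(min_chain, max_chain + 1))
    length = max(length, len(fragments) + 1)
    positions = rng.choice(length, size=len(fragments), replace=False)
    slots = [""] * length
    for pos, frag in zip(positions, fragments):
        slots[int(pos)] = f"({frag})"
    smiles = "".join(f"C{s}" for s in slots)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _noise_prevalences(n: int) -> np.ndarray:
    """Annotation rates for the uninformative terms.

    Real functional ontologies are dominated by terms annotated for almost
    no metabolite (near-zero dispersion), with a minority at moderate
    prevalence; dispersion-based selection relies on exactly that shape.
    Most noise terms therefore sit at 0.1-1% prevalence, plus four
    mid-prevalence terms (5-30%) so the selection stage sees structureless
    columns on both sides of the outlier threshold.
    """
    if n == 0:
        return np.zeros(0)
    if n < 8:
        return np.geomspace(0.002, 0.3, n)
    return np.concatenate([np.geomspace(0.001, 0.01, n - 4),
                           [0.05, 0.1, 0.2, 0.3]])


def _ontology_tree(spec: FixtureSpec, noise_terms: dict[str, str]) -> OntologyTree:
    tree = OntologyTree()
    for cat in CATEGORIES:
        tree.add_node(cat, parent=None, category=cat)
        slug = cat.lower().replace(" ", "-")
        tree.add_node(f"{slug}-structural", parent=cat)
        tree.add_node(f"{slug}-misc", parent=cat)
    for m in spec.motifs:
        slug = m.category.lower().replace(" ", "-")
        tree.add_node(m.term_id, parent=f"{slug}-structural")
    for term, cat in noise_terms.items():
        slug = cat.lower().replace(" ", "-")
        tree.add_node(term, parent=f"{slug}-misc")
    tree.validate()
    return tree


def generate_dataset(spec: FixtureSpec, out_dir=None) -> SyntheticDataset:
    """Generate molecules, annotations and (optionally) on-disk artifacts.

    Deterministic under ``spec.seed``: repeated calls produce byte-identical
    XML/SDF/manifest files.  When ``out_dir`` is given, writes
    ``metabolites.xml``, ``structures/<id>.sdf``, ``ontology.json`` and
    ``manifest.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    noise_prev = _noise_prevalences(spec.n_noise_labels)
    noise_terms = {
        f"noise-{i:02d}": CATEGORIES[i % len(CATEGORIES)]
        for i in range(spec.n_noise_labels)
    }
    tree = _ontology_tree(spec, noise_terms)
    motif_queries = {m.term_id: Chem.MolFromSmiles(m.fragment) for m in spec.motifs}

    statuses = list(spec.status_mix)
    status_p = np.array([spec.status_mix[s] for s in statuses])

    records: list[MetaboliteRecord] = []
    manifest_mols = {}
    for i in range(spec.n_molecules):
        mol_id = f"SYN{i + 1:05d}"
        smiles = None
        for _ in range(20):  # bounded retries for invalid constructions
            chosen = [m for m in spec.motifs
                      if rng.random() < m.attach_probability]
            smiles = _build_molecule(rng, [m.fragment for m in chosen],
                                     spec.min_chain, spec.max_chain)
            if smiles is not None:
                break
        if smiles is None:
            raise RuntimeError(f"could not build a valid molecule for {mol_id}")
        mol = Chem.MolFromSmiles(smiles)
        # ground truth by substructure match, independent of construction
        contains = {t: bool(mol.HasSubstructMatch(q))
                    for t, q in motif_queries.items()}
        flipped = {t: bool(v ^ (rng.random() < spec.label_noise_rate))
                   for t, v in contains.items()}
        noise_on = {t: bool(rng.random() < p)
                    for t, p in zip(noise_terms, noise_prev)}
        status = statuses[int(rng.choice(len(statuses), p=status_p))]

        term_ids: set[str] = set()
        for t, on in {**flipped, **noise_on}.items():
            if on:
                term_ids.add(t)
                term_ids.update(tree.ancestors(t))
        records.append(MetaboliteRecord(mol_id, smiles, status, term_ids))
        manifest_mols[mol_id] = {
            "smiles": smiles,
            "status": status.value,
            "contains_motif": contains,
            "labels_after_noise": flipped,
            "noise_labels": noise_on,
        }

    manifest = {
        "seed": spec.seed,
        "n_molecules": spec.n_molecules,
        "label_noise_rate": spec.label_noise_rate,
        "motifs": [{"fragment": m.fragment, "term_id": m.term_id,
                    "category": m.category,
                    "attach_probability": m.attach_probability}
                   for m in spec.motifs],
        "noise_prevalences": {t: float(p)
                              for t, p in zip(noise_terms, noise_prev)},
        "molecules": manifest_mols,
    }
    ds = SyntheticDataset(records, tree, manifest, spec)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hmdb_xml(records, tree, out / "metabolites.xml")
        sdf_dir = out / "structures"
        sdf_dir.mkdir(exist_ok=True)
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            AllChem.Compute2DCoords(mol)
            (sdf_dir / f"{rec.metabolite_id}.sdf").write_text(
                Chem.MolToMolBlock(mol) + "$$$$\n")
        from .ingest import write_tree_json

        write_tree_json(tree, out / "ontology.json")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return ds


def make_unit_fixtures() -> dict:
    """Tiny hand-written fixtures with known expected outputs.

    * ``records``/``tree``: three metabolites (ethanol, glycine, benzoic
      acid) annotated in a 2-level ontology.
    * ``mad_table``: a 5 x 4 truth table whose column dispersions select
      exactly one term under the modified-Z rule (the all-zero column, via
      the low-sigma tail of the absolute-value criterion).
    """
    tree = OntologyTree()
    for cat in CATEGORIES:
        tree.add_node(cat, parent=None, category=cat)
    tree.add_node("u-alcohols", parent="Disposition")
    tree.add_node("u-ethanol-like", parent="u-alcohols")
    tree.add_node("u-amino", parent="Role")
    tree.add_node("u-aromatic", parent="Process")
    tree.add_node("u-acidic", parent="Physiological effect")
    tree.validate()

    records = [
        MetaboliteRecord("UNIT0001", "CCO", DetectionStatus.detected_quantified,
                         {"Disposition", "u-alcohols", "u-ethanol-like"},
                         name="ethanol"),
        MetaboliteRecord("UNIT0002", "NCC(=O)O", DetectionStatus.detected_quantified,
                         {"Role", "u-amino", "Physiological effect", "u-acidic"},
                         name="glycine"),
        MetaboliteRecord("UNIT0003", "OC(=O)c1ccccc1", DetectionStatus.expected,
                         {"Process", "u-aromatic", "Physiological effect",
                          "u-acidic"}, name="benzoic acid"),
    ]

    # columns: positives k = 1, 1, 2, 0 out of N = 5
    mad_table = TruthTable(
        ["M1", "M2", "M3", "M4", "M5"],
        ["t-one-a", "t-one-b", "t-two", "t-never"],
        np.array([
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
        ]),
    )
    return {"records": records, "tree": tree, "mad_table": mad_table,
            "mad_expected_selected": ["t-never"]}
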