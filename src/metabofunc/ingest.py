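"""Reading and writing metabolite datasets.

Parses metabolite XML in a documented subset of the HMDB export dialect
(``metabolite``/``accession``/``smiles``/``status``/``ontology`` with nested
``root``/``descendant``/``term`` elements), attaches 2D depiction coordinates
from per-metabolite SDF/MOL files, and builds the binary truth table.  The
same writer emits the dialect, so synthetic datasets flow through the exact
parser used for real exports.

No statistics live here; filtering and selection are in
:mod:`metabofunc.label_selection`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from rdkit import Chem
from rdkit.Chem import AllChem

from .datatypes import (
    CATEGORIES,
    DetectionStatus,
    MetaboliteRecord,
    OntologyTree,
    TruthTable,
)

__all__ = [
    "parse_hmdb_xml",
    "write_hmdb_xml",
    "attach_coordinates",
    "build_truth_table",
    "CoordinateReport",
]


class HmdbParseError(ValueError):
    pass


def _parse_term_subtree(elem, parent_id: str | None, category: str,
                        tree: OntologyTree, term_ids: set[str]) -> None:
    term_el = elem.find("term")
    if term_el is None or not (term_el.text or "").strip():
        raise HmdbParseError(f"ontology element without <term> at line {elem.sourceline}")
    term = term_el.text.strip()
    tree.add_node(term, parent=parent_id, category=category)
    term_ids.add(term)
    desc = elem.find("descendants")
    if desc is not None:
        for child in desc.findall("descendant"):
            _parse_term_subtree(child, term, category, tree, term_ids)


def parse_hmdb_xml(path, limit: int | None = None) -> tuple[list[MetaboliteRecord], OntologyTree]:
    """Parse a metabolite XML export into records and the accumulated ontology.

    Records lacking a SMILES are returned flagged ``missing_smiles``, never
    silently dropped.  Parsing is deterministic: document order is preserved.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise HmdbParseError(f"malformed XML in {path}: {exc}") from exc

    tree = OntologyTree()
    for cat in CATEGORIES:
        tree.add_node(cat, parent=None, category=cat)

    records: list[MetaboliteRecord] = []
    for met in doc.getroot().iter("metabolite"):
        if limit is not None and len(records) >= limit:
            break
        accession = (met.findtext("accession") or "").strip()
        if not accession:
            raise HmdbParseError(f"metabolite without accession at line {met.sourceline}")
        raw_status = (met.findtext("status") or "").strip()
        try:
            status = DetectionStatus.parse(raw_status)
        except ValueError as exc:
            raise HmdbParseError(f"metabolite {accession}: {exc}") from exc
        smiles = (met.findtext("smiles") or "").strip()
        term_ids: set[str] = set()
        onto = met.find("ontology")
        if onto is not None:
            for root_el in onto.findall("root"):
                cat = (root_el.findtext("term") or "").strip()
                if cat not in CATEGORIES:
                    raise HmdbParseError(
                        f"metabolite {accession}: unknown ontology root {cat!r}"
                    )
                _parse_term_subtree(root_el, None, cat, tree, term_ids)
        records.append(
            MetaboliteRecord(
                metabolite_id=accession,
                smiles=smiles,
                status=status,
                term_ids=term_ids,
                name=(met.findtext("name") or "").strip(),
            )
        )
    tree.validate()
    return records, tree


def _subtree_xml(parent_el, term: str, children_of: dict[str, list[str]], tag: str) -> None:
    el = etree.SubElement(parent_el, tag)
    etree.SubElement(el, "term").text = term
    kids = children_of.get(term, [])
    if kids:
        desc = etree.SubElement(el, "descendants")
        for kid in kids:
            _subtree_xml(desc, kid, children_of, "descendant")


def write_hmdb_xml(records: list[MetaboliteRecord], tree: OntologyTree, path) -> None:
    """Write records in the fixture dialect read by :func:`parse_hmdb_xml`.

    A record's annotated terms are written as the minimal nested subtree
    containing them, closed under ancestors (as HMDB exports list full
    paths), so ancestor-closed annotation sets round-trip identically.
    """
    root = etree.Element("metabolites")
    for rec in records:
        met = etree.SubElement(root, "metabolite")
        etree.SubElement(met, "accession").text = rec.metabolite_id
        if rec.name:
            etree.SubElement(met, "name").text = rec.name
        etree.SubElement(met, "status").text = rec.status.value
        etree.SubElement(met, "smiles").text = rec.smiles
        closed: set[str] = set()
        for t in rec.term_ids:
            closed.add(t)
            closed.update(tree.ancestors(t))
        if closed:
            # restricted child map over the closure, deterministic order
            children_of: dict[str, list[str]] = {}
            for t in sorted(closed):
                p = tree.nodes[t].parent
                if p is not None:
                    children_of.setdefault(p, []).append(t)
            onto = etree.SubElement(met, "ontology")
            for cat in CATEGORIES:
                if cat in closed or children_of.get(cat):
                    _subtree_xml(onto, cat, children_of, "root")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------- coordinates


@dataclass
class CoordinateReport:
    from_file: int = 0
    computed: int = 0
    mismatched: int = 0
    unparseable: int = 0
    details: list[str] = field(default_factory=list)


def computed_2d_coords(smiles: str) -> list[tuple[float, float]] | None:
    """Deterministic 2D layout for a SMILES (heavy atoms, parser atom order)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    return [(conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
            for i in range(mol.GetNumAtoms())]


def attach_coordinates(
    records: list[MetaboliteRecord], sdf_dir=None
) -> tuple[list[MetaboliteRecord], CoordinateReport]:
    """Populate 2D coordinates, preferring per-metabolite SDF/MOL files.

    Coordinates are reordered to the atom order of the record's SMILES (via
    substructure matching), so downstream featurization can rely on a single
    canonical atom ordering.  Missing files, unparseable structures and
    heavy-atom-count mismatches fall back to a computed layout and are
    counted in the report.
    """
    report = CoordinateReport()
    sdf_dir = Path(sdf_dir) if sdf_dir is not None else None
    for rec in records:
        if "missing_smiles" in rec.flags:
            report.unparseable += 1
            continue
        smi_mol = Chem.MolFromSmiles(rec.smiles)
        if smi_mol is None:
            rec.flags.add("unparseable_smiles")
            report.unparseable += 1
            continue
        coords = None
        if sdf_dir is not None:
            for ext in (".sdf", ".mol"):
                f = sdf_dir / f"{rec.metabolite_id}{ext}"
                if f.exists():
                    file_mol = Chem.MolFromMolFile(str(f))
                    if file_mol is None:
                        report.details.append(f"{rec.metabolite_id}: unreadable {f.name}")
                        break
                    if file_mol.GetNumAtoms() != smi_mol.GetNumAtoms():
                        rec.flags.add("coord_mismatch")
                        report.mismatched += 1
                        report.details.append(
                            f"{rec.metabolite_id}: atom count {file_mol.GetNumAtoms()} "
                            f"in {f.name} vs {smi_mol.GetNumAtoms()} in SMILES"
                        )
                        break
                    match = file_mol.GetSubstructMatch(smi_mol)
                    if len(match) != smi_mol.GetNumAtoms():
                        rec.flags.add("coord_mismatch")
                        report.mismatched += 1
                        break
                    conf = file_mol.GetConformer()
                    coords = [
                        (conf.GetAtomPosition(j).x, conf.GetAtomPosition(j).y)
                        for j in match
                    ]
                    break
        if coords is not None:
            rec.coords = coords
            report.from_file += 1
        else:
            rec.coords = computed_2d_coords(rec.smiles)
            rec.flags.add("computed_coords")
            report.computed += 1
    return records, report


# ----------------------------------------------------------------- truth table


def build_truth_table(
    records: list[MetaboliteRecord],
    tree: OntologyTree,
    term_subset: set[str] | None = None,
    propagate: bool = False,
) -> TruthTable:
    """Binary annotation matrix; columns in sorted term-id order.

    By default every ontology term gets a column, including terms no
    record is annotated with: all-zero columns are real data (zero
    dispersion) for the downstream term selection, exactly like the many
    never-annotated terms of a full ontology.  With ``propagate`` enabled,
    a term counts as annotated when any of its descendants is annotated.
    Default is off: outputs are predicted on the terms exactly as annotated.
    """
    if not records:
        raise ValueError("empty dataset")
    if term_subset is not None:
        missing = term_subset - set(tree.nodes)
        if missing:
            raise ValueError(f"terms not in ontology: {sorted(missing)}")
        terms = sorted(term_subset)
    else:
        terms = sorted(tree.nodes)
    values = np.zeros((len(records), len(terms)), dtype=np.int8)
    desc_cache = {t: tree.descendants(t) for t in terms} if propagate else None
    for i, rec in enumerate(records):
        for j, t in enumerate(terms):
            hit = t in rec.term_ids
            if propagate and not hit:
                hit = bool(desc_cache[t] & rec.term_ids)
            values[i, j] = 1 if hit else 0
    return TruthTable([r.metabolite_id for r in records], terms, values)


def write_tree_json(tree: OntologyTree, path) -> None:
    Path(path).write_text(json.dumps(tree.to_json_dict(), indent=2, sort_keys=True))


def read_tree_json(path) -> OntologyTree:
    return OntologyTree.from_json_dict(json.loads(Path(path).read_text()))
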