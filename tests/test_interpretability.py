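"""Attention-based bond attribution and substructure enrichment."""

import numpy as np
import pytest

from metabofunc.interpretability import (
    AttributionMap,
    enrichment_permutation_test,
    explain_molecule,
    render_attribution,
    substructure_enrichment,
    weight_to_color,
)
from metabofunc.model import MetaboliteFunctionModel, ModelSpec, featurize_dataset

from conftest import rng_for


@pytest.fixture(scope="module")
def gat(small_ds, small_split):
    table, selected, plan = small_split
    ds = featurize_dataset(small_ds.records, table, selected, True, None, None)
    ds = ds.subset(ds.ids[:50])
    spec = ModelSpec(arch="gat", n_labels=len(selected), epochs=3, seed=13)
    return ds, MetaboliteFunctionModel(ds, spec).fit()


def test_non_gat_model_rejected(small_ds, small_split):
    table, selected, _ = small_split
    ds = featurize_dataset(small_ds.records, table, selected, True, None, None)
    ds = ds.subset(ds.ids[:10])
    res = MetaboliteFunctionModel(
        ds, ModelSpec(arch="gcn", n_labels=len(selected), epochs=1)).fit()
    with pytest.raises(ValueError, match="attention not available"):
        explain_molecule(res, ds.graphs[0])


def test_scaled_weights_span_unit_interval(gat):
    ds, res = gat
    for g in ds.graphs[:10]:
        m = explain_molecule(res, g)
        assert len(m.bonds) == g.n_bonds
        assert m.scaled_weights.min() >= 0 and m.scaled_weights.max() <= 1
        if not m.degenerate:
            assert m.scaled_weights.min() == 0.0
            assert m.scaled_weights.max() == 1.0


def test_single_bond_molecule_is_degenerate_one(gat):
    from metabofunc.datatypes import DetectionStatus, MetaboliteRecord
    from metabofunc.featurization import molecule_to_graph

    ds, res = gat
    rec = MetaboliteRecord("METHANOL", "CO", DetectionStatus.detected_quantified)
    g = molecule_to_graph(rec, ds.vocab, ds.scaler, True)
    m = explain_molecule(res, g)
    assert m.degenerate
    assert m.scaled_weights.tolist() == [1.0]


def test_max_over_heads_matches_bruteforce_tensor_max(gat):
    ds, res = gat
    g = ds.graphs[0]
    m = explain_molecule(res, g, layer=1)
    conv = res.net.convs[0]
    alpha, ei = conv.last_alpha, conv.last_edge_index
    merged = {}
    for e in range(ei.shape[1]):
        key = tuple(sorted((int(ei[0, e]), int(ei[1, e]))))
        merged[key] = max(merged.get(key, -np.inf), float(alpha[e].max()))
    assert m.bonds == sorted(merged)
    assert np.allclose(m.raw_weights, [merged[b] for b in m.bonds])


def test_explanation_deterministic(gat):
    ds, res = gat
    a = explain_molecule(res, ds.graphs[1])
    b = explain_molecule(res, ds.graphs[1])
    assert np.array_equal(a.scaled_weights, b.scaled_weights)


def test_layer_out_of_range_rejected(gat):
    ds, res = gat
    with pytest.raises(ValueError, match="layer"):
        explain_molecule(res, ds.graphs[0], layer=3)


# -------------------------------------------------------------- enrichment


def map_for(smiles, weights_by_bond):
    """Build an AttributionMap by hand for a SMILES molecule."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                   for b in mol.GetBonds())
    w = np.array([weights_by_bond[b] for b in bonds])
    return AttributionMap("X", bonds, w, w, np.zeros(1, dtype=np.int8), 1)


def test_all_weight_on_matched_bonds_maximizes_inside():
    # propionic acid: put all weight on the carboxyl bonds
    smiles = "CCC(=O)O"
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    acid = set()
    for match in mol.GetSubstructMatches(Chem.MolFromSmiles("C(=O)O")):
        ms = set(match)
        for b in mol.GetBonds():
            u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if u in ms and v in ms:
                acid.add((min(u, v), max(u, v)))
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                   for b in mol.GetBonds())
    weights = {b: (1.0 if b in acid else 0.0) for b in bonds}
    m = map_for(smiles, weights)
    rep = substructure_enrichment([m], "C(=O)O", {"X": smiles})
    assert rep["per_molecule"]["X"]["inside"] == 1.0
    assert rep["per_molecule"]["X"]["outside"] == 0.0
    assert rep["fraction_inside_greater"] == 1.0


def test_uniform_random_weights_show_no_enrichment():
    rng = rng_for("null-enrichment")
    smiles = "CCCCC(=O)O"
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                   for b in mol.GetBonds())
    maps, ids = [], {}
    for i in range(300):
        w = {b: rng.random() for b in bonds}
        m = map_for(smiles, w)
        m.mol_id = f"X{i}"
        ids[m.mol_id] = smiles
        maps.append(m)
    rep = substructure_enrichment(maps, "C(=O)O", ids)
    assert abs(rep["fraction_inside_greater"] - 0.5) < 0.1


def test_unmatched_pattern_rejected():
    m = map_for("CCO", {(0, 1): 0.5, (1, 2): 0.6})
    with pytest.raises(ValueError, match="matched no bonds"):
        substructure_enrichment([m], "c1ccccc1", {"X": "CCO"})


def test_permutation_test_pvalue_bounds():
    rng = rng_for("perm-bounds")
    smiles = "CCCC(=O)O"
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                   for b in mol.GetBonds())
    maps, ids = [], {}
    for i in range(20):
        w = {b: rng.random() for b in bonds}
        m = map_for(smiles, w)
        m.mol_id = f"X{i}"
        ids[m.mol_id] = smiles
        maps.append(m)
    res = enrichment_permutation_test(maps, "C(=O)O", ids, n_permutations=50,
                                      seed=3)
    assert 0 < res["p_value"] <= 1
    assert 0 <= res["null_mean"] <= 1


# ----------------------------------------------------------------- render


def test_color_ramp_endpoints():
    assert weight_to_color(0.0) == (1.0, 1.0, 1.0)  # white
    assert weight_to_color(1.0) == (1.0, 0.0, 0.0)  # full red


def test_render_is_deterministic_svg(gat, tmp_path, small_ds):
    ds, res = gat
    smiles = small_ds.smiles_by_id()
    g = ds.graphs[0]
    m = explain_molecule(res, g)
    p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
    render_attribution(m, smiles[g.mol_id], p1)
    render_attribution(m, smiles[g.mol_id], p2)
    svg = p1.read_text()
    assert svg.startswith("<?xml") and "<svg" in svg
    assert p1.read_bytes() == p2.read_bytes()
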