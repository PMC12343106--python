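"""Dispersion statistics and MAD/modified-Z label selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabofunc.datatypes import CATEGORIES, OntologyTree, TruthTable
from metabofunc.label_selection import (
    LabelFilterConfig,
    MADZeroError,
    leaf_terms,
    modified_z_scores,
    per_term_std,
    select_labels,
)

from conftest import rng_for


# ------------------------------------------------------- brute-force oracle


def oracle_select(values: np.ndarray, term_ids, z_constant=0.6745,
                  z_threshold=3.5):
    """Independent reimplementation: plain loops, no shared code paths.

    For binary columns sum_i (x - xbar)^2 reduces exactly to k(n-k)/n with
    k the positive count, so sigma comes from integer counts (the same
    exact reduction the library uses, via an independent code path).
    """
    import math

    n = values.shape[0]
    stds = []
    for j in range(values.shape[1]):
        k_pos = sum(int(v) for v in values[:, j])
        stds.append(math.sqrt((k_pos * (n - k_pos)) / (n * (n - 1))))

    def median(xs):
        xs = sorted(xs)
        mid = len(xs) // 2
        return xs[mid] if len(xs) % 2 else (xs[mid - 1] + xs[mid]) / 2

    med = median(stds)
    mad = median([abs(s - med) for s in stds])
    if mad == 0:
        raise ZeroDivisionError
    out = []
    for t, s in zip(term_ids, stds):
        m = z_constant * (s - med) / mad
        if abs(m) > z_threshold:
            out.append(t)
    return sorted(out), stds


def flat_tree(term_ids, category="Process"):
    tree = OntologyTree()
    for cat in CATEGORIES:
        tree.add_node(cat, parent=None, category=cat)
    for t in term_ids:
        tree.add_node(t, parent=category)
    return tree


# ---------------------------------------------------------------- leaf terms


def test_leaf_terms_of_a_chain_is_the_deepest_node():
    tree = flat_tree([])
    tree.add_node("A", parent="Process")
    tree.add_node("B", parent="A")
    assert leaf_terms(tree, "Process") == ["B"]


def test_leaf_terms_mix_of_depths():
    tree = flat_tree([])
    for t, p in [("L1", "Role"), ("L2", "Role"), ("I", "Role"), ("L3", "I")]:
        tree.add_node(t, parent=p)
    assert leaf_terms(tree, "Role") == ["L1", "L2", "L3"]


def test_childless_category_warns_and_returns_empty():
    tree = flat_tree([], category="Process")
    with pytest.warns(UserWarning, match="no descendant"):
        assert leaf_terms(tree, "Physiological effect") == []


def test_unknown_category_rejected():
    with pytest.raises(ValueError):
        leaf_terms(flat_tree(["x"]), "Metabolism")


# -------------------------------------------------------------------- sigma


@pytest.mark.parametrize("col,expected", [
    ([0, 0, 0, 0], 0.0),
    ([1, 1, 1, 1], 0.0),
    ([1, 0, 0, 0], 0.5),  # sqrt((0.75^2 + 3*0.25^2)/3)
])
def test_sample_std_of_binary_columns(col, expected):
    table = TruthTable([f"m{i}" for i in range(4)], ["t"],
                       np.array(col).reshape(-1, 1))
    assert per_term_std(table)["t"] == pytest.approx(expected)


def test_std_requires_two_metabolites():
    table = TruthTable(["m0"], ["t"], np.array([[1]]))
    with pytest.raises(ValueError, match="insufficient"):
        per_term_std(table)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_sigma_invariant_under_row_permutation(seed):
    rng = np.random.default_rng(seed)
    values = (rng.random((8, 5)) < 0.3).astype(int)
    terms = [f"t{j}" for j in range(5)]
    table = TruthTable([f"m{i}" for i in range(8)], terms, values)
    perm = rng.permutation(8)
    shuffled = TruthTable([f"m{i}" for i in perm], terms, values[perm])
    assert per_term_std(table) == per_term_std(shuffled)


# ----------------------------------------------------------- modified Z


def test_median_term_scores_zero():
    scores = modified_z_scores({"a": 1.0, "b": 2.0, "c": 3.0})
    assert scores["b"] == 0.0


def test_identical_stds_raise_mad_zero():
    with pytest.raises(MADZeroError):
        modified_z_scores({"a": 0.3, "b": 0.3, "c": 0.3})


def test_outlier_score_matches_hand_evaluation():
    # stds [1,2,3,4,100]: median 3, MAD 1 -> M_last = 0.6745 * 97
    scores = modified_z_scores({f"t{i}": s for i, s in enumerate([1, 2, 3, 4, 100])})
    assert scores["t4"] == pytest.approx(0.6745 * 97)
    assert scores["t0"] == pytest.approx(0.6745 * -2)


# -------------------------------------------------------------- selection


def test_threshold_is_strictly_greater(unit):
    table, tree = unit["mad_table"], flat_tree(unit["mad_table"].term_ids)
    sel = select_labels(table, tree, category="Process")
    # raising the threshold to exactly |M| of the selected term excludes it
    m = abs(sel.per_term_mscore[sel.selected[0]])
    at_boundary = select_labels(
        table, tree, LabelFilterConfig(z_threshold=m), "Process")
    assert sel.selected[0] not in at_boundary.selected


def test_unit_fixture_selects_exactly_one_term(unit):
    table = unit["mad_table"]
    tree = flat_tree(table.term_ids)
    sel = select_labels(table, tree, category="Process")
    assert sel.selected == unit["mad_expected_selected"] == ["t-never"]
    expected, stds = oracle_select(table.values, table.term_ids)
    assert sel.selected == expected
    assert sel.n_low_tail == 1 and sel.n_high_tail == 0
    for t, s in zip(table.term_ids, stds):
        assert sel.per_term_std[t] == pytest.approx(s)


def test_selection_restricted_to_leaves(unit):
    # internal group nodes never appear among selected terms
    tree = flat_tree(["leafA", "leafB"])
    tree.add_node("inner", parent="Process")
    tree.add_node("leafC", parent="inner")
    values = np.zeros((20, 4), dtype=int)
    values[:10, 0] = 1  # inner
    values[:2, 1] = 1   # leafA
    values[:5, 2] = 1   # leafB
    values[:8, 3] = 1   # leafC
    table = TruthTable([f"m{i}" for i in range(20)],
                       ["inner", "leafA", "leafB", "leafC"], values)
    sel = select_labels(table, tree, category="Process")
    assert "inner" not in sel.per_term_std
    assert set(sel.per_term_std) == {"leafA", "leafB", "leafC"}


def test_empty_selection_is_valid_with_warning():
    tree = flat_tree(["a", "b", "c", "d"])
    rng = rng_for("empty-selection")
    values = (rng.random((30, 4)) < [0.4, 0.45, 0.5, 0.55]).astype(int)
    table = TruthTable([f"m{i}" for i in range(30)], list("abcd"), values)
    with pytest.warns(UserWarning, match="no term"):
        sel = select_labels(table, tree, category="Process")
    assert sel.selected == []


def test_select_matches_bruteforce_on_random_tables():
    rng = rng_for("oracle-tables")
    checked = 0
    for _ in range(100):
        n = int(rng.integers(5, 50))
        k = int(rng.integers(3, 30))
        prev = rng.uniform(0, 0.6, size=k)
        values = (rng.random((n, k)) < prev).astype(int)
        terms = [f"t{j:02d}" for j in range(k)]
        table = TruthTable([f"m{i}" for i in range(n)], terms, values)
        tree = flat_tree(terms)
        try:
            expected, _ = oracle_select(values, terms)
        except ZeroDivisionError:
            with pytest.raises(MADZeroError):
                select_labels(table, tree, category="Process")
            continue
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            sel = select_labels(table, tree, category="Process")
        assert sel.selected == expected
        checked += 1
    assert checked > 50


def test_constant_column_leaves_other_sigmas_unchanged():
    rng = rng_for("constant-column")
    values = (rng.random((15, 4)) < 0.3).astype(int)
    terms = ["a", "b", "c", "d"]
    base = TruthTable([f"m{i}" for i in range(15)], terms, values)
    widened = TruthTable(base.metabolite_ids, terms + ["const"],
                         np.hstack([values, np.ones((15, 1), dtype=int)]))
    s0 = per_term_std(base)
    s1 = per_term_std(widened)
    assert all(s1[t] == s0[t] for t in terms)
    assert s1["const"] == 0.0
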