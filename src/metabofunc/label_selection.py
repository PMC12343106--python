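"""Dispersion-based selection of ontology terms to predict.

Most ontology terms are annotated for almost no metabolites (or for nearly
all), so their per-term standard deviation across the detected-and-quantified
metabolites is close to zero and they carry no signal for a classifier.  The
selection pipeline is:

1. restrict the truth table to leaf terms of one functional category;
2. compute the sample standard deviation sigma_j of every binary column,
   sigma_j = sqrt( sum_i (x_ij - xbar_j)^2 / (N - 1) );
3. convert the sigma vector to modified Z-scores
   M_i = 0.6745 * (s_i - median(s)) / MAD(s),
   with MAD the median absolute deviation of the sigmas;
4. keep terms with |M_i| strictly greater than 3.5.

The absolute-value rule is kept verbatim even though the low-sigma tail
(large negative M) flags uninformative terms; how many selected terms came
from each tail is reported so the caller can audit the selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import CATEGORIES, DetectionStatus, OntologyTree, TruthTable

logger = logging.getLogger(__name__)

__all__ = [
    "LabelFilterConfig",
    "LabelSelection",
    "MADZeroError",
    "leaf_terms",
    "per_term_std",
    "modified_z_scores",
    "select_labels",
    "per_status_std_report",
]


class MADZeroError(ValueError):
    pass


@dataclass
class LabelFilterConfig:
    z_constant: float = 0.6745
    z_threshold: float = 3.5
    ddof: int = 1  # sample standard deviation, N-1 denominator
    status_filter: DetectionStatus = DetectionStatus.detected_quantified

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")


@dataclass
class LabelSelection:
    category: str
    per_term_std: dict[str, float]
    per_term_mscore: dict[str, float]
    selected: list[str]
    n_high_tail: int = 0
    n_low_tail: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "category": self.category,
            "per_term_std": self.per_term_std,
            "per_term_mscore": self.per_term_mscore,
            "selected": self.selected,
            "n_high_tail": self.n_high_tail,
            "n_low_tail": self.n_low_tail,
            "warnings": self.warnings,
        }


def leaf_terms(tree: OntologyTree, category: str) -> list[str]:
    """Childless descendants of one category root, sorted by term id."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category not in tree.nodes:
        raise ValueError(f"category {category!r} absent from ontology")
    desc = tree.descendants(category)
    if not desc:
        warnings.warn(f"category {category!r} has no descendant terms", stacklevel=2)
        return []
    return sorted(t for t in desc if not tree.children(t))


def per_term_std(table: TruthTable, config: LabelFilterConfig | None = None) -> dict[str, float]:
    """Per-column standard deviation of the binary annotation values.

    sigma_j = sqrt( sum_i (x_ij - xbar_j)^2 / (N - ddof) ).  For a binary
    column with k positives the sum of squared deviations is exactly
    k(N - k)/N, so sigma is computed from the count: this is order
    insensitive and bit-reproducible (columns with equal k get bitwise
    equal sigmas, which matters for the downstream MAD).
    """
    config = config or LabelFilterConfig()
    n = len(table.metabolite_ids)
    if n - config.ddof < 1:
        raise ValueError(f"insufficient metabolites (N={n}) for ddof={config.ddof}")
    k = table.values.astype(np.int64).sum(axis=0)
    stds = np.sqrt(k * (n - k) / (n * (n - config.ddof)))
    return {t: float(s) for t, s in zip(table.term_ids, stds)}


def modified_z_scores(stds: dict[str, float], config: LabelFilterConfig | None = None) -> dict[str, float]:
    """Modified Z-score of each term's sigma against the median/MAD of all sigmas."""
    config = config or LabelFilterConfig()
    if not stds:
        raise ValueError("no terms")
    terms = list(stds)
    s = np.array([stds[t] for t in terms], dtype=np.float64)
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    if mad == 0.0:
        raise MADZeroError("degenerate dispersion: MAD is zero")
    m = config.z_constant * (s - med) / mad
    return {t: float(v) for t, v in zip(terms, m)}


def select_labels(
    table: TruthTable,
    tree: OntologyTree,
    config: LabelFilterConfig | None = None,
    category: str | None = None,
) -> LabelSelection | dict[str, LabelSelection]:
    """Select output terms for one category (or all four when ``category=None``).

    ``table`` must already be restricted to the metabolites of
    ``config.status_filter`` (detected and quantified by default); this
    function performs no row filtering.
    """
    config = config or LabelFilterConfig()
    if category is None:
        return {c: select_labels(table, tree, config, c) for c in CATEGORIES}

    leaves = leaf_terms(tree, category)
    notes: list[str] = []
    present = [t for t in leaves if t in table.term_ids]
    absent = len(leaves) - len(present)
    if absent:
        notes.append(f"{absent} leaf terms of {category!r} absent from truth table")
    if not present:
        notes.append(f"no leaf terms of {category!r} in truth table; empty selection")
        warnings.warn(notes[-1], stacklevel=2)
        return LabelSelection(category, {}, {}, [], warnings=notes)

    sub = table.restrict_terms(present)
    stds = per_term_std(sub, config)
    try:
        scores = modified_z_scores(stds, config)
    except MADZeroError:
        raise
    selected = sorted(t for t, m in scores.items() if abs(m) > config.z_threshold)
    if not selected:
        notes.append(f"no term of {category!r} exceeds |M| > {config.z_threshold}")
        warnings.warn(notes[-1], stacklevel=2)
    high = sum(1 for t in selected if scores[t] > 0)
    low = len(selected) - high
    logger.info(
        "category %s: %d terms selected (%d high-sigma tail, %d low-sigma tail)",
        category, len(selected), high, low,
    )
    return LabelSelection(category, stds, scores, selected,
                          n_high_tail=high, n_low_tail=low, warnings=notes)


def per_status_std_report(
    records, tree: OntologyTree, config: LabelFilterConfig | None = None
) -> dict[str, dict[str, float]]:
    """Per-term sigma within each detection-status group (reporting only).

    Reproduces the rationale histograms showing that terms have near-zero
    dispersion outside the detected-and-quantified group; it plays no part
    in selection.
    """
    from .ingest import build_truth_table

    config = config or LabelFilterConfig()
    out: dict[str, dict[str, float]] = {}
    all_terms = {t for r in records for t in r.term_ids}
    for status in DetectionStatus:
        group = [r for r in records if r.status == status]
        if len(group) - config.ddof < 1:
            out[status.value] = {}
            continue
        table = build_truth_table(group, tree, term_subset=all_terms & set(tree.nodes))
        out[status.value] = per_term_std(table, config)
    return out
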