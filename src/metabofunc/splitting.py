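"""Output-cluster train/test splitting and cross-validation folds.

Metabolites sharing an identical selected-label vector form one cluster;
each cluster is split 0.9/0.1 (train/test), which guarantees that every
label carried by a cluster of size >= 2 appears on both sides of the split.
Cross-validation folds are dealt round-robin within each shuffled cluster so
label composition stays balanced across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import TruthTable

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "cluster_by_output", "split_clusters", "make_cv_folds"]


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    ratio: float = 0.9
    fold_assignments: dict[str, int] | None = None
    label_coverage_violations: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "seed": self.seed,
            "ratio": self.ratio,
            "fold_assignments": self.fold_assignments,
            "label_coverage_violations": self.label_coverage_violations,
        }


def cluster_by_output(table: TruthTable, selected: list[str]) -> list[list[str]]:
    """Group metabolites whose restricted label vectors are identical.

    Clusters are sorted by size descending, ties broken by the
    lexicographically first metabolite id, so the ordering is deterministic.
    """
    missing = set(selected) - set(table.term_ids)
    if missing:
        raise ValueError(f"selected terms not in table: {sorted(missing)}")
    idx = [table.term_ids.index(t) for t in selected]
    groups: dict[tuple, list[str]] = {}
    for i, mid in enumerate(table.metabolite_ids):
        key = tuple(int(v) for v in table.values[i, idx])
        groups.setdefault(key, []).append(mid)
    clusters = [sorted(v) for v in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def split_clusters(clusters: list[list[str]], ratio: float = 0.9, seed: int = 0,
                   table: TruthTable | None = None,
                   selected: list[str] | None = None) -> SplitPlan:
    """Split every cluster train/test at ``ratio``, seeded and deterministic.

    Clusters of size >= 2 send ``max(1, round((1-ratio)*size))`` members to
    test (half-up rounding, guarded against float representation of the
    ratio; never more than size-1); singletons go entirely to train, since a
    label seen in one metabolite only must at least be trainable.  When the
    truth table and selected labels are supplied, the both-sides coverage
    guarantee is checked post hoc for labels carried by any cluster of
    size >= 2 and violations are reported on the plan.
    """
    if not clusters:
        raise ValueError("empty cluster list")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cluster in clusters:
        members = list(cluster)
        rng.shuffle(members)
        if len(members) == 1:
            train.extend(members)
            continue
        frac = round((1 - ratio) * len(members), 9)
        n_test = min(len(members) - 1, max(1, int(np.floor(frac + 0.5))))
        test.extend(members[:n_test])
        train.extend(members[n_test:])
    plan = SplitPlan(sorted(train), sorted(test), seed=seed, ratio=ratio)

    if table is not None and selected is not None:
        eligible = set()
        for cluster in clusters:
            if len(cluster) >= 2:
                eligible.update(cluster)
        train_set, test_set = set(plan.train_ids), set(plan.test_ids)
        for t in selected:
            col = table.column(t)
            carriers = {m for m, v in zip(table.metabolite_ids, col) if v}
            if not carriers & eligible:
                continue  # only singleton carriers: guarantee cannot apply
            if not (carriers & train_set) or not (carriers & test_set):
                plan.label_coverage_violations.append(t)
        if plan.label_coverage_violations:
            logger.warning("labels missing from one side of the split: %s",
                           plan.label_coverage_violations)
    return plan


def make_cv_folds(clusters: list[list[str]], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign metabolites to k folds, round-robin within each shuffled cluster.

    The starting fold rotates across clusters so small clusters do not pile
    into fold 0.  Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_total = sum(len(c) for c in clusters)
    if n_total < k:
        raise ValueError(f"fewer metabolites ({n_total}) than folds ({k})")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cluster in clusters:
        members = list(cluster)
        rng.shuffle(members)
        for i, mid in enumerate(members):
            assignment[mid] = (offset + i) % k
        offset = (offset + len(members)) % k
    counts = np.bincount(list(assignment.values()), minlength=k)
    if (counts == 0).any():
        # possible only with tiny datasets; rebalance deterministically
        order = sorted(assignment)
        for fold in np.flatnonzero(counts == 0):
            donor = max(range(k), key=lambda f: counts[f])
            mover = next(m for m in order if assignment[m] == donor)
            assignment[mover] = int(fold)
            counts[donor] -= 1
            counts[fold] += 1
    return assignment
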