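"""Metrics, cross-validated model comparison and ablation studies.

Because annotations are sparse and false negatives abound, accuracy is
avoided; the panel is recall, macro F1, support-weighted F1 and macro
average precision (area under the precision-recall curve, rectangle rule).
Model comparison runs the eight variants (GCN/GIN/GAT with and without
pretrained molecule embeddings, fingerprint-MLP baseline, embedding-MLP)
under five-fold cross-validation with shared hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_fscore_support

from .model import (
    FeaturizedDataset,
    FunctionPredictionResults,
    MetaboliteFunctionModel,
    ModelSpec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "compute_metrics",
    "cross_validate",
    "run_ablation",
    "comparison_heatmap",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("recall", "macro_f1", "weighted_f1", "auprc")


@dataclass
class MetricReport:
    per_label: dict[str, dict[str, float]]
    recall_macro: float
    macro_f1: float
    weighted_f1: float
    auprc_macro: float
    warnings: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float]:
        return {
            "recall": self.recall_macro,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "auprc": self.auprc_macro,
        }


def compute_metrics(
    truth: np.ndarray,
    probs: np.ndarray,
    threshold: float = 0.5,
    label_ids: list[str] | None = None,
) -> MetricReport:
    """Multilabel metric panel at a strict decision threshold (p > t).

    Per-label precision/recall/F1 use a zero-division policy of 0 (no
    predicted positives or no true positives score zero, with a warning);
    macro values are unweighted means over labels, weighted F1 weights by
    the label's positive support.  AP of a label without positives is 0.
    """
    truth = np.asarray(truth)
    probs = np.asarray(probs, dtype=np.float64)
    if truth.shape != probs.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {probs.shape}")
    if truth.ndim == 1:
        truth, probs = truth[:, None], probs[:, None]
    n_labels = truth.shape[1]
    if label_ids is None:
        label_ids = [f"label_{j}" for j in range(n_labels)]
    pred = (probs > threshold).astype(np.int8)

    # per column with average='binary' so a single-label matrix is not
    # collapsed into per-class (negative/positive) scores
    notes = []
    prec = np.zeros(n_labels)
    rec = np.zeros(n_labels)
    f1 = np.zeros(n_labels)
    support = np.zeros(n_labels, dtype=int)
    ap = np.zeros(n_labels)
    for j in range(n_labels):
        prec[j], rec[j], f1[j], _ = precision_recall_fscore_support(
            truth[:, j], pred[:, j], average="binary", pos_label=1,
            zero_division=0,
        )
        support[j] = int(truth[:, j].sum())
        if support[j] == 0:
            notes.append(f"label {label_ids[j]} has no positives; F1/AP set to 0")
            ap[j] = 0.0
        else:
            ap[j] = average_precision_score(truth[:, j], probs[:, j])
    if notes:
        logger.warning("; ".join(notes))

    per_label = {
        label_ids[j]: {
            "precision": float(prec[j]),
            "recall": float(rec[j]),
            "f1": float(f1[j]),
            "support": int(support[j]),
            "average_precision": float(ap[j]),
        }
        for j in range(n_labels)
    }
    total = support.sum()
    weighted = float((f1 * support).sum() / total) if total > 0 else 0.0
    return MetricReport(
        per_label=per_label,
        recall_macro=float(rec.mean()),
        macro_f1=float(f1.mean()),
        weighted_f1=weighted,
        auprc_macro=float(ap.mean()),
        warnings=notes,
    )


def _spec_row_name(spec: ModelSpec) -> str:
    base = {"gcn": "GCN", "gin": "GIN", "gat": "GAT",
            "mlp_fp": "Baseline", "mlp_emb": "MLP"}[spec.arch]
    if spec.is_graph and spec.use_chemberta:
        return base + "C"
    return base


def default_comparison_specs(n_labels: int, use_coords: bool = True,
                             seed: int = 0, **overrides) -> list[ModelSpec]:
    """The eight compared variants, shared hyperparameters."""
    specs = []
    for arch in ("mlp_fp", "mlp_emb", "gcn", "gin", "gat"):
        specs.append(ModelSpec(arch=arch, n_labels=n_labels,
                               use_coords=use_coords, seed=seed, **overrides))
    for arch in ("gcn", "gin", "gat"):
        specs.append(ModelSpec(arch=arch, n_labels=n_labels, use_chemberta=True,
                               use_coords=use_coords, seed=seed, **overrides))
    return specs


def _fit_eval(dataset: FeaturizedDataset, spec: ModelSpec,
              train_ids: list[str], eval_ids: list[str]) -> MetricReport:
    train = dataset.subset(train_ids)
    hold = dataset.subset(eval_ids)
    results = MetaboliteFunctionModel(train, spec).fit()
    probs = results.predict_proba(hold)
    missing = [t for j, t in enumerate(dataset.label_ids)
               if hold.labels[:, j].sum() == 0]
    if missing:
        logger.warning("fold missing positives for labels %s", missing)
    return compute_metrics(hold.labels, probs, spec.decision_threshold,
                           dataset.label_ids)


def cross_validate(
    dataset: FeaturizedDataset,
    specs: list[ModelSpec],
    fold_assignments: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV of each spec; rows indexed by variant name, mean +/- sd.

    Fold assignments come from :func:`metabofunc.splitting.make_cv_folds`;
    every spec sees identical folds.  Returns a tidy frame with columns
    ``<metric>_mean`` and ``<metric>_sd``.
    """
    folds = sorted(set(fold_assignments.values()))
    rows = {}
    for spec in specs:
        per_fold = []
        for f in folds:
            train_ids = [m for m in dataset.ids if fold_assignments.get(m, -1) != f]
            eval_ids = [m for m in dataset.ids if fold_assignments.get(m, -1) == f]
            spec_f = ModelSpec(**{**vars(spec), "seed": spec.seed + seed})
            per_fold.append(_fit_eval(dataset, spec_f, train_ids, eval_ids).as_row())
        row = {}
        for m in METRIC_COLUMNS:
            vals = np.array([p[m] for p in per_fold])
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows[_spec_row_name(spec)] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def run_ablation(
    dataset_with: FeaturizedDataset,
    base_spec: ModelSpec,
    mode: str,
    fold_assignments: dict[str, int],
    seed: int = 0,
    dataset_without: FeaturizedDataset | None = None,
) -> dict[str, pd.DataFrame]:
    """Matched with/without comparison for coordinates or embeddings.

    ``mode='coords'`` drops the two coordinate columns (node features go
    from N x (M+2) to N x M) and needs ``dataset_without`` featurized with
    ``use_coords=False``; ``mode='embeddings'`` drops the pretrained vector
    from the fully connected input.  Identical folds and seeds on both
    sides; the delta table is with-minus-without, entrywise.
    """
    if not base_spec.is_graph:
        raise ValueError("ablation applies to graph architectures")
    if mode == "coords":
        if dataset_without is None:
            raise ValueError("mode='coords' requires dataset_without "
                             "(featurized with use_coords=False)")
        spec_with = ModelSpec(**{**vars(base_spec), "use_coords": True})
        spec_without = ModelSpec(**{**vars(base_spec), "use_coords": False})
        ds_with, ds_without = dataset_with, dataset_without
    elif mode == "embeddings":
        if not base_spec.use_chemberta:
            raise ValueError("mode='embeddings' requires use_chemberta=True "
                             "in base_spec (nothing to ablate)")
        spec_with = base_spec
        spec_without = ModelSpec(**{**vars(base_spec), "use_chemberta": False})
        ds_with = ds_without = dataset_with
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")

    tab_with = cross_validate(ds_with, [spec_with], fold_assignments, seed)
    tab_without = cross_validate(ds_without, [spec_without], fold_assignments, seed)
    tab_without.index = tab_with.index
    delta = tab_with - tab_without
    return {"with": tab_with, "without": tab_without, "delta": delta}


def comparison_heatmap(tables: dict[str, pd.DataFrame], path) -> None:
    """Save a models-by-metrics heatmap, one block per category."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(tables)
    fig, axes = plt.subplots(1, len(cats), figsize=(3.2 * len(cats), 4),
                             squeeze=False)
    for ax, cat in zip(axes[0], cats):
        df = tables[cat][[f"{m}_mean" for m in METRIC_COLUMNS]]
        im = ax.imshow(df.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(METRIC_COLUMNS)), METRIC_COLUMNS, rotation=45,
                      ha="right", fontsize=7)
        ax.set_yticks(range(len(df.index)), df.index, fontsize=7)
        ax.set_title(cat, fontsize=9)
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                ax.text(j, i, f"{df.iat[i, j]:.2f}", ha="center", va="center",
                        fontsize=6, color="white")
    fig.colorbar(im, ax=axes[0].tolist(), shrink=0.7)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
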