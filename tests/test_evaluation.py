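"""Metric panel, cross-validation bookkeeping and ablations."""

import numpy as np
import pytest

from metabofunc.evaluation import (
    METRIC_COLUMNS,
    compute_metrics,
    cross_validate,
    default_comparison_specs,
    run_ablation,
)
from metabofunc.model import MetaboliteFunctionModel, ModelSpec, featurize_dataset
from metabofunc.splitting import make_cv_folds

from conftest import rng_for


# ----------------------------------------------------- independent oracle


def oracle_metrics(truth, probs, threshold=0.5):
    """Hand-coded confusion-matrix / PR-curve implementation."""
    truth = np.asarray(truth)
    pred = (np.asarray(probs) > threshold).astype(int)
    n_labels = truth.shape[1]
    f1s, recalls, supports, aps = [], [], [], []
    for j in range(n_labels):
        tp = int(((pred[:, j] == 1) & (truth[:, j] == 1)).sum())
        fp = int(((pred[:, j] == 1) & (truth[:, j] == 0)).sum())
        fn = int(((pred[:, j] == 0) & (truth[:, j] == 1)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1s.append(f1)
        recalls.append(rec)
        supports.append(tp + fn)
        # AP by the step-wise rectangle rule over the ranked list
        if tp + fn == 0:
            aps.append(0.0)
            continue
        order = np.argsort(-probs[:, j], kind="stable")
        y = truth[order, j]
        p_j = probs[order, j]
        ap, hits, prev_recall = 0.0, 0, 0.0
        i = 0
        while i < len(y):
            # process ties in the score as one group
            k = i
            while k < len(y) and p_j[k] == p_j[i]:
                k += 1
            hits += int(y[i:k].sum())
            recall = hits / (tp + fn)
            precision = hits / k
            ap += (recall - prev_recall) * precision
            prev_recall = recall
            i = k
        aps.append(ap)
    total = sum(supports)
    return {
        "macro_f1": sum(f1s) / n_labels,
        "weighted_f1": (sum(f * s for f, s in zip(f1s, supports)) / total
                        if total else 0.0),
        "recall": sum(recalls) / n_labels,
        "auprc": sum(aps) / n_labels,
    }


def test_perfect_predictions_score_one():
    truth = np.array([[1, 0], [0, 1], [1, 1]])
    probs = truth * 0.8 + 0.1
    rep = compute_metrics(truth, probs)
    assert rep.macro_f1 == 1.0
    assert rep.recall_macro == 1.0
    assert rep.auprc_macro == 1.0


def test_all_wrong_predictions_score_zero():
    truth = np.array([[1, 0], [0, 1]])
    probs = 1.0 - (truth * 0.8 + 0.1)
    rep = compute_metrics(truth, probs)
    assert rep.macro_f1 == 0.0


def test_hand_computed_two_label_confusion():
    # label 0: TP=2 FP=1 FN=1 -> P=2/3 R=1/2 F1=4/7
    # label 1: TP=1 FP=0 FN=2 -> P=1   R=1/3 F1=1/2
    truth = np.array([[1, 1], [1, 1], [1, 1], [0, 0], [0, 0], [1, 0]])
    probs = np.array([[.9, .9], [.8, .1], [.2, .2], [.7, .1], [.1, .1], [.2, .3]])
    rep = compute_metrics(truth, probs)
    assert rep.per_label["label_0"]["f1"] == pytest.approx(4 / 7)
    assert rep.per_label["label_1"]["f1"] == pytest.approx(1 / 2)
    assert rep.macro_f1 == pytest.approx((4 / 7 + 1 / 2) / 2)
    assert rep.weighted_f1 == pytest.approx((4 * 4 / 7 + 3 * 1 / 2) / 7)


def test_metrics_match_independent_oracle_on_random_inputs():
    rng = rng_for("metric-oracle")
    for _ in range(50):
        n = int(rng.integers(5, 100))
        k = int(rng.integers(1, 8))
        truth = (rng.random((n, k)) < 0.35).astype(int)
        probs = np.round(rng.random((n, k)), 3)  # rounded to force ties
        rep = compute_metrics(truth, probs)
        exp = oracle_metrics(truth, probs)
        assert rep.macro_f1 == pytest.approx(exp["macro_f1"], abs=1e-9)
        assert rep.weighted_f1 == pytest.approx(exp["weighted_f1"], abs=1e-9)
        assert rep.recall_macro == pytest.approx(exp["recall"], abs=1e-9)
        assert rep.auprc_macro == pytest.approx(exp["auprc"], abs=1e-9)


def test_average_precision_invariant_to_monotone_transform():
    rng = rng_for("ap-monotone")
    truth = (rng.random((60, 3)) < 0.3).astype(int)
    probs = rng.random((60, 3))
    a = compute_metrics(truth, probs).auprc_macro
    b = compute_metrics(truth, 1 / (1 + np.exp(-5 * probs))).auprc_macro
    assert a == pytest.approx(b, abs=1e-12)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        compute_metrics(np.zeros((3, 2)), np.zeros((3, 3)))


def test_zero_positive_label_scores_zero_with_warning():
    truth = np.array([[1, 0], [0, 0], [1, 0]])
    probs = np.full((3, 2), 0.4)
    rep = compute_metrics(truth, probs)
    assert rep.per_label["label_1"]["average_precision"] == 0.0
    assert any("no positives" in w for w in rep.warnings)


# ------------------------------------------------------- cross-validation


@pytest.fixture(scope="module")
def cv_setup(small_ds, small_split):
    table, selected, plan = small_split
    ds = featurize_dataset(small_ds.records, table, selected, True, None, None)
    ds = ds.subset(ds.ids[:60])
    folds = make_cv_folds([[m] for m in ds.ids], k=3, seed=1)
    return ds, folds


def test_cross_validation_bookkeeping(cv_setup):
    ds, folds = cv_setup
    specs = [ModelSpec(arch=a, n_labels=len(ds.label_ids), epochs=1, seed=1)
             for a in ("gcn", "mlp_fp")]
    table = cross_validate(ds, specs, folds)
    assert list(table.index) == ["GCN", "Baseline"]
    for m in METRIC_COLUMNS:
        assert f"{m}_mean" in table.columns and f"{m}_sd" in table.columns
    assert table.notna().all().all()


def test_cv_mean_equals_recomputed_fold_mean(cv_setup):
    ds, folds = cv_setup
    spec = ModelSpec(arch="mlp_fp", n_labels=len(ds.label_ids), epochs=2, seed=3)
    table = cross_validate(ds, [spec], folds)
    from metabofunc.evaluation import _fit_eval

    per_fold = []
    for f in sorted(set(folds.values())):
        train = [m for m in ds.ids if folds[m] != f]
        hold = [m for m in ds.ids if folds[m] == f]
        per_fold.append(_fit_eval(ds, spec, train, hold).macro_f1)
    assert table.loc["Baseline", "macro_f1_mean"] == pytest.approx(
        np.mean(per_fold))


def test_cv_deterministic_under_seed(cv_setup):
    ds, folds = cv_setup
    spec = ModelSpec(arch="mlp_fp", n_labels=len(ds.label_ids), epochs=1, seed=2)
    t1 = cross_validate(ds, [spec], folds)
    t2 = cross_validate(ds, [spec], folds)
    assert t1.equals(t2)


def test_default_comparison_covers_eight_variants():
    specs = default_comparison_specs(n_labels=4)
    names = [(s.arch, s.use_chemberta) for s in specs]
    assert len(names) == 8
    assert names.count(("gat", True)) == 1 and names.count(("mlp_fp", False)) == 1


# --------------------------------------------------------------- ablation


def test_coordinate_ablation_pairs_and_delta(small_ds, small_split):
    table, selected, _ = small_split
    with_c = featurize_dataset(small_ds.records, table, selected, True, None, None)
    without = featurize_dataset(small_ds.records, table, selected, False, None, None)
    with_c, without = with_c.subset(with_c.ids[:40]), without.subset(without.ids[:40])
    assert (with_c.graphs[0].node_features.shape[1]
            - without.graphs[0].node_features.shape[1]) == 2
    folds = make_cv_folds([[m] for m in with_c.ids], k=2, seed=0)
    spec = ModelSpec(arch="gcn", n_labels=len(selected), epochs=1, seed=0)
    res = run_ablation(with_c, spec, "coords", folds, dataset_without=without)
    delta = res["with"] - res["without"]
    assert np.allclose(res["delta"].to_numpy(), delta.to_numpy())


def test_embedding_ablation_requires_embeddings_in_spec(cv_setup):
    ds, folds = cv_setup
    spec = ModelSpec(arch="gat", n_labels=len(ds.label_ids), epochs=1)
    with pytest.raises(ValueError, match="nothing to ablate"):
        run_ablation(ds, spec, "embeddings", folds)


def test_ablation_rejects_mlp(cv_setup):
    ds, folds = cv_setup
    with pytest.raises(ValueError, match="graph"):
        run_ablation(ds, ModelSpec(arch="mlp_fp", n_labels=len(ds.label_ids)),
                     "coords", folds)


# ------------------------------------------------------------ signal sanity


def test_models_beat_label_permuted_control(small_ds, small_split):
    table, selected, plan = small_split
    ds = featurize_dataset(small_ds.records, table, selected, True, None,
                           plan.train_ids)
    train, test = ds.subset(plan.train_ids), ds.subset(plan.test_ids)
    rng = rng_for("permuted-control")
    shuffled = train.subset(train.ids)
    shuffled.labels = shuffled.labels[rng.permutation(len(shuffled))]
    spec = ModelSpec(arch="gcn", n_labels=len(selected), epochs=8, seed=6)
    real = MetaboliteFunctionModel(train, spec).fit()
    control = MetaboliteFunctionModel(shuffled, spec).fit()
    f1_real = compute_metrics(test.labels, real.predict_proba(test)).macro_f1
    f1_ctrl = compute_metrics(test.labels, control.predict_proba(test)).macro_f1
    assert f1_real > f1_ctrl
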