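"""End-to-end orchestration: ingest -> filter -> split -> featurize -> train
-> evaluate (-> ablate/explain).

The only module allowed to chain the others.  Every stage writes its
artifact plus a JSON log line; re-running with the same config and seed
reproduces all numeric outputs byte-for-byte (metrics are serialized with
sorted keys and repr-exact floats).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .datatypes import DetectionStatus
from .embeddings import EmbeddingProvider
from .evaluation import compute_metrics, cross_validate, run_ablation
from .ingest import (
    attach_coordinates,
    build_truth_table,
    parse_hmdb_xml,
    write_tree_json,
)
from .label_selection import LabelFilterConfig, select_labels
from .model import MetaboliteFunctionModel, ModelSpec, featurize_dataset
from .splitting import cluster_by_output, make_cv_folds, split_clusters

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, last_artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed after {last_artifact!r}: {cause}")
        self.stage = stage
        self.last_artifact = last_artifact


@dataclass
class RunConfig:
    xml_path: str
    out_dir: str
    category: str = "Process"
    sdf_dir: str | None = None
    z_threshold: float = 3.5
    split_ratio: float = 0.9
    cv_folds: int = 5
    evaluation: str = "holdout"  # holdout | cv | ablation
    arch: str = "gat"
    use_coords: bool = True
    use_chemberta: bool = False
    embedding_backend: str = "deterministic_stub"
    epochs: int = 20
    lr: float = 0.005
    weight_decay: float = 0.001
    hidden_dim: int = 32
    node_feature_dim: int = 64
    attention_heads: int = 8
    batch_size: int = 32
    decision_threshold: float = 0.5
    label_ids: list[str] | None = None  # override MAD selection when given
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


class _Logger:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.t0 = time.time()

    def stage(self, name: str, artifact: str, **extra) -> None:
        line = {"stage": name, "artifact": artifact, "config": self.config_hash,
                "elapsed_s": round(time.time() - self.t0, 3), **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(line, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    chash = hashlib.sha256(config.to_json().encode()).hexdigest()[:12]
    log = _Logger(out / "run.log", chash)
    last = "config.json"

    def guard(stage):
        def wrap(fn, *args, **kwargs):
            nonlocal last
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(stage, last, exc) from exc
            return result
        return wrap

    # ingest
    records, tree = guard("ingest")(parse_hmdb_xml, config.xml_path)
    records, coord_report = guard("ingest")(attach_coordinates, records,
                                            config.sdf_dir)
    write_tree_json(tree, out / "ontology.json")
    log.stage("ingest", "ontology.json", n_records=len(records),
              coords_from_file=coord_report.from_file,
              coords_computed=coord_report.computed)
    last = "ontology.json"

    # status filter: only detected-and-quantified metabolites are modeled
    dq = [r for r in records
          if r.status == DetectionStatus.detected_quantified
          and "missing_smiles" not in r.flags
          and "unparseable_smiles" not in r.flags]
    table = guard("truth_table")(build_truth_table, dq, tree)
    table.to_tsv(out / "truth_table.tsv")
    log.stage("truth_table", "truth_table.tsv", n_metabolites=len(dq),
              n_terms=len(table.term_ids), density=round(table.density, 6))
    last = "truth_table.tsv"

    # label selection
    if config.label_ids is not None:
        selected = list(config.label_ids)
        _dump_json({"category": config.category, "selected": selected,
                    "source": "config override"}, out / "selection.json")
    else:
        cfg = LabelFilterConfig(z_threshold=config.z_threshold)
        selection = guard("label_selection")(select_labels, table, tree, cfg,
                                             config.category)
        selected = selection.selected
        _dump_json(selection.to_json_dict(), out / "selection.json")
    log.stage("label_selection", "selection.json", n_selected=len(selected))
    last = "selection.json"
    if not selected:
        raise PipelineError("label_selection", last,
                            ValueError("no labels selected; nothing to train"))

    # cluster split
    clusters = guard("split")(cluster_by_output, table, selected)
    plan = guard("split")(split_clusters, clusters, config.split_ratio,
                          config.seed, table, selected)
    plan.fold_assignments = guard("split")(
        make_cv_folds,
        [[m for m in c if m in set(plan.train_ids)] for c in clusters
         if set(c) & set(plan.train_ids)],
        config.cv_folds, config.seed)
    _dump_json(plan.to_json_dict(), out / "plan.json")
    log.stage("split", "plan.json", n_train=len(plan.train_ids),
              n_test=len(plan.test_ids))
    last = "plan.json"

    # featurize
    provider = None
    if config.use_chemberta or config.arch == "mlp_emb":
        provider = EmbeddingProvider(backend=config.embedding_backend)
    dataset = guard("featurize")(
        featurize_dataset, dq, table, selected,
        config.use_coords, provider, plan.train_ids)
    log.stage("featurize", "(in-memory tensors)", n_molecules=len(dataset),
              vocab=dataset.vocab.elements)
    last = "featurized dataset"

    spec = ModelSpec(
        arch=config.arch, n_labels=len(selected),
        use_chemberta=config.use_chemberta, use_coords=config.use_coords,
        epochs=config.epochs, lr=config.lr, weight_decay=config.weight_decay,
        hidden_dim=config.hidden_dim, node_feature_dim=config.node_feature_dim,
        attention_heads=config.attention_heads, batch_size=config.batch_size,
        decision_threshold=config.decision_threshold, seed=config.seed,
    )

    metrics: dict = {"category": config.category, "labels": selected}
    if config.evaluation == "holdout":
        train = dataset.subset([m for m in plan.train_ids if m in set(dataset.ids)])
        test = dataset.subset([m for m in plan.test_ids if m in set(dataset.ids)])
        results = guard("train")(MetaboliteFunctionModel(train, spec).fit)
        results.save(out / "model")
        log.stage("train", "model/", final_loss=results.training_log[-1])
        last = "model/"
        probs, _ = results.predict(test)
        report = compute_metrics(test.labels, probs, spec.decision_threshold,
                                 selected)
        metrics["holdout"] = {"n_test": len(test), **report.as_row(),
                              "per_label": report.per_label}
    elif config.evaluation == "cv":
        train = dataset.subset([m for m in plan.train_ids if m in set(dataset.ids)])
        tab = guard("cross_validate")(cross_validate, train, [spec],
                                      plan.fold_assignments, 0)
        metrics["cv"] = json.loads(tab.to_json(orient="index"))
    elif config.evaluation == "ablation":
        ds_nc = guard("featurize")(
            featurize_dataset, dq, table, selected, False, provider,
            plan.train_ids)
        train = dataset.subset([m for m in plan.train_ids if m in set(dataset.ids)])
        train_nc = ds_nc.subset([m for m in plan.train_ids if m in set(ds_nc.ids)])
        res = guard("ablation")(run_ablation, train, spec, "coords",
                                plan.fold_assignments, 0, train_nc)
        metrics["ablation_coords"] = {
            k: json.loads(v.to_json(orient="index")) for k, v in res.items()}
    else:
        raise PipelineError("evaluate", last,
                            ValueError(f"unknown evaluation mode {config.evaluation!r}"))

    _dump_json(metrics, out / "metrics.json")
    log.stage("evaluate", "metrics.json", mode=config.evaluation)
    return out
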