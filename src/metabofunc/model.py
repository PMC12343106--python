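"""Multilabel metabolite-function classifiers.

The modelling surface follows the statsmodels convention: a
:class:`MetaboliteFunctionModel` is built from a featurized dataset plus a
:class:`ModelSpec`, its :meth:`~MetaboliteFunctionModel.fit` runs the
training loop and returns a :class:`FunctionPredictionResults` object
carrying the fitted weights, the training log, prediction methods and a
``summary()`` table.

Five architectures are available, all ending in a per-label logistic
output:

* ``gcn`` / ``gin`` / ``gat`` -- node-feature projection, two graph
  convolutions of the named family, sum-aggregation readout, optionally the
  pretrained molecule embedding concatenated before the fully connected
  head.  The GAT uses 8 attention heads and consumes bond-type edge
  features; GCN/GIN have no mechanism for edge features and ignore them.
* ``mlp_fp`` -- three linear layers on the 1024-bit circular fingerprint
  (baseline).
* ``mlp_emb`` -- three linear layers on the 600-dim molecule embedding.

Training uses Adam with binary cross-entropy, fixed epoch count, no early
stopping; all randomness (weight init, batch order) derives from the spec
seed, so CPU runs are bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .datatypes import MetaboliteRecord, TruthTable
from .embeddings import EmbeddingProvider, embed_batch
from .featurization import (
    AtomVocabulary,
    CoordinateScaler,
    GraphBatch,
    MoleculeGraph,
    batch_graphs,
    build_vocabulary,
    circular_fingerprint,
    molecule_to_graph,
    normalize_molecule_coords,
)

__all__ = [
    "ModelSpec",
    "FeaturizedDataset",
    "featurize_dataset",
    "MetaboliteFunctionModel",
    "FunctionPredictionResults",
]

ARCHS = ("gcn", "gin", "gat", "mlp_fp", "mlp_emb")


@dataclass
class ModelSpec:
    """Architecture choice plus the shared training hyperparameters.

    Defaults are the study's settings: 2 convolutional layers, 64 node
    features, 32 hidden units, 8 attention heads, 20 epochs, decision
    threshold 0.5, learning rate 0.005, weight decay 0.001.
    """

    arch: str
    n_labels: int
    n_conv_layers: int = 2
    node_feature_dim: int = 64
    hidden_dim: int = 32
    attention_heads: int = 8
    use_chemberta: bool = False
    use_coords: bool = True
    decision_threshold: float = 0.5
    lr: float = 0.005
    weight_decay: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    embedding_dim: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")

    @property
    def is_graph(self) -> bool:
        return self.arch in ("gcn", "gin", "gat")


class _GraphNet(nn.Module):
    def __init__(self, spec: ModelSpec, in_dim: int, rng: np.random.Generator):
        self.spec = spec
        self.proj = nn.Linear(in_dim, spec.node_feature_dim, rng)
        self.convs: list[nn.Module] = []
        width = spec.node_feature_dim
        for layer in range(spec.n_conv_layers):
            last = layer == spec.n_conv_layers - 1
            if spec.arch == "gcn":
                conv = nn.GCNConv(width, spec.hidden_dim, rng)
                width = spec.hidden_dim
            elif spec.arch == "gin":
                conv = nn.GINConv(width, spec.hidden_dim, rng)
                width = spec.hidden_dim
            else:  # gat: concatenate heads between layers, average at the last
                conv = nn.GATConv(
                    width, spec.hidden_dim, spec.attention_heads, rng,
                    concat_heads=not last, edge_dim=4,
                )
                width = spec.hidden_dim * (1 if last else spec.attention_heads)
            self.convs.append(conv)
        fc_in = width + (spec.embedding_dim if spec.use_chemberta else 0)
        self.fc = nn.Linear(fc_in, spec.n_labels, rng)

    def forward(self, batch: GraphBatch, emb: np.ndarray | None) -> Tensor:
        h = self.proj(Tensor(batch.node_features))
        for i, conv in enumerate(self.convs):
            h = conv(h, batch.edge_index, batch.edge_type)
            if i < len(self.convs) - 1:
                h = h.relu()
        pooled = nn.sum_pool(h, batch.batch, batch.n_graphs)
        if self.spec.use_chemberta:
            if emb is None:
                raise ValueError("spec.use_chemberta=True but no embeddings supplied")
            pooled = concat([pooled, Tensor(emb)], axis=1)
        return self.fc(pooled)


class _MLPNet(nn.Module):
    """Three linear layers: input -> 4*hidden -> hidden -> labels."""

    def __init__(self, spec: ModelSpec, in_dim: int, rng: np.random.Generator):
        self.spec = spec
        self.lin1 = nn.Linear(in_dim, spec.hidden_dim * 4, rng)
        self.lin2 = nn.Linear(spec.hidden_dim * 4, spec.hidden_dim, rng)
        self.lin3 = nn.Linear(spec.hidden_dim, spec.n_labels, rng)

    def forward(self, x: np.ndarray) -> Tensor:
        h = self.lin1(Tensor(x)).relu()
        h = self.lin2(h).relu()
        return self.lin3(h)


@dataclass
class FeaturizedDataset:
    """Aligned per-metabolite tensors ready for any of the architectures."""

    ids: list[str]
    graphs: list[MoleculeGraph]
    fingerprints: np.ndarray
    labels: np.ndarray
    label_ids: list[str]
    vocab: AtomVocabulary
    scaler: CoordinateScaler
    embeddings: np.ndarray | None = None
    use_coords: bool = True

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "FeaturizedDataset":
        pos = {m: i for i, m in enumerate(self.ids)}
        idx = [pos[m] for m in ids]
        return FeaturizedDataset(
            ids=list(ids),
            graphs=[self.graphs[i] for i in idx],
            fingerprints=self.fingerprints[idx],
            labels=self.labels[idx],
            label_ids=list(self.label_ids),
            vocab=self.vocab,
            scaler=self.scaler,
            embeddings=None if self.embeddings is None else self.embeddings[idx],
            use_coords=self.use_coords,
        )


def featurize_dataset(
    records: list[MetaboliteRecord],
    table: TruthTable,
    label_ids: list[str],
    use_coords: bool = True,
    provider: EmbeddingProvider | None = None,
    fit_ids: list[str] | None = None,
    cache_path=None,
) -> FeaturizedDataset:
    """Featurize records whose ids appear in ``table``.

    The coordinate scaler is fitted on ``fit_ids`` (the training molecules)
    only; all records are then transformed with it.
    """
    by_id = {r.metabolite_id: r for r in records}
    ids = [m for m in table.metabolite_ids if m in by_id]
    recs = [by_id[m] for m in ids]
    vocab, failed = build_vocabulary(recs)
    if failed:
        ids = [m for m in ids if m not in set(failed)]
        recs = [by_id[m] for m in ids]

    scaler = CoordinateScaler()
    if use_coords:
        fit_set = set(fit_ids) if fit_ids is not None else set(ids)
        from .ingest import computed_2d_coords

        normalized = []
        for r in recs:
            if r.metabolite_id not in fit_set:
                continue
            coords = r.coords if r.coords is not None else computed_2d_coords(r.smiles)
            normalized.append(normalize_molecule_coords(coords))
        if not normalized:
            raise ValueError("no molecules available to fit the coordinate scaler")
        scaler.fit(normalized)

    graphs = [molecule_to_graph(r, vocab, scaler, use_coords) for r in recs]
    fps = np.stack([circular_fingerprint(r.smiles) for r in recs])
    sub = table.restrict_rows(ids).restrict_terms(label_ids)
    labels = sub.values.astype(np.float64)
    emb = None
    if provider is not None:
        emb, _ = embed_batch(provider, [r.smiles for r in recs], cache_path)
    return FeaturizedDataset(ids, graphs, fps, labels, list(label_ids), vocab,
                             scaler, emb, use_coords)


class MetaboliteFunctionModel:
    """Multilabel classifier for the selected terms of one category."""

    def __init__(self, dataset: FeaturizedDataset, spec: ModelSpec):
        if spec.n_labels != len(dataset.label_ids):
            raise ValueError(
                f"spec.n_labels={spec.n_labels} but dataset has "
                f"{len(dataset.label_ids)} labels"
            )
        if spec.is_graph and spec.use_chemberta and dataset.embeddings is None:
            raise ValueError("use_chemberta=True requires dataset embeddings")
        if spec.arch == "mlp_emb" and dataset.embeddings is None:
            raise ValueError("mlp_emb requires dataset embeddings")
        if spec.is_graph and dataset.graphs:
            width = dataset.graphs[0].node_features.shape[1]
            expected = dataset.vocab.size + (2 if spec.use_coords else 0)
            if width != expected:
                raise ValueError(
                    f"node-feature width {width} does not match spec "
                    f"(expected {expected}); refeaturize with use_coords="
                    f"{spec.use_coords}"
                )
        self.dataset = dataset
        self.spec = spec

    def _build_net(self, rng: np.random.Generator) -> nn.Module:
        spec = self.spec
        if spec.is_graph:
            in_dim = self.dataset.vocab.size + (2 if spec.use_coords else 0)
            return _GraphNet(spec, in_dim, rng)
        in_dim = (self.dataset.fingerprints.shape[1] if spec.arch == "mlp_fp"
                  else spec.embedding_dim)
        return _MLPNet(spec, in_dim, rng)

    def fit(self, verbose: bool = False) -> "FunctionPredictionResults":
        spec = self.spec
        ds = self.dataset
        rng = np.random.default_rng(spec.seed)
        net = self._build_net(rng)
        opt = nn.Adam(net.parameters(), lr=spec.lr, weight_decay=spec.weight_decay)
        n = len(ds)
        log: list[float] = []
        t0 = time.time()
        for epoch in range(spec.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, spec.batch_size):
                idx = order[start:start + spec.batch_size]
                y = ds.labels[idx]
                if spec.is_graph:
                    gb = batch_graphs([ds.graphs[i] for i in idx])
                    emb = None if not spec.use_chemberta else ds.embeddings[idx]
                    logits = net.forward(gb, emb)
                else:
                    x = (ds.fingerprints[idx] if spec.arch == "mlp_fp"
                         else ds.embeddings[idx])
                    logits = net.forward(x)
                loss = nn.bce_with_logits(logits, y)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // spec.batch_size}"
                        f" (lr={spec.lr})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                weights.append(len(idx))
            log.append(float(np.average(losses, weights=weights)))
            if verbose:
                print(f"epoch {epoch + 1:3d}/{spec.epochs}  loss {log[-1]:.4f}")
        return FunctionPredictionResults(
            model=self, net=net, training_log=log, fit_seconds=time.time() - t0
        )


class FunctionPredictionResults:
    """Fitted parameters, training log and prediction interface."""

    def __init__(self, model: MetaboliteFunctionModel, net: nn.Module,
                 training_log: list[float], fit_seconds: float = 0.0):
        self.model = model
        self.net = net
        self.training_log = training_log
        self.fit_seconds = fit_seconds

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def label_ids(self) -> list[str]:
        return self.model.dataset.label_ids

    @property
    def params(self) -> list[np.ndarray]:
        return self.net.state_arrays()

    # ------------------------------------------------------------- predict
    def predict_proba(self, dataset: FeaturizedDataset) -> np.ndarray:
        spec = self.spec
        n = len(dataset)
        if n == 0:
            return np.zeros((0, spec.n_labels))
        out = []
        for start in range(0, n, spec.batch_size):
            sl = slice(start, start + spec.batch_size)
            if spec.is_graph:
                gb = batch_graphs(dataset.graphs[sl])
                emb = None if not spec.use_chemberta else dataset.embeddings[sl]
                logits = self.net.forward(gb, emb)
            else:
                x = (dataset.fingerprints[sl] if spec.arch == "mlp_fp"
                     else dataset.embeddings[sl])
                logits = self.net.forward(x)
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out, axis=0)

    def predict(self, dataset: FeaturizedDataset) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and the strict-threshold binary decisions (p > t)."""
        probs = self.predict_proba(dataset)
        return probs, (probs > self.spec.decision_threshold).astype(np.int8)

    def predict_graphs(self, graphs: list[MoleculeGraph],
                       emb: np.ndarray | None = None) -> np.ndarray:
        if not graphs:
            return np.zeros((0, self.spec.n_labels))
        if not self.spec.is_graph:
            raise ValueError("predict_graphs requires a graph architecture")
        logits = self.net.forward(batch_graphs(graphs), emb)
        return 1.0 / (1.0 + np.exp(-logits.data))

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        spec = self.spec
        n_params = sum(p.size for p in self.params)
        lines = [
            "Metabolite function prediction results",
            "=" * 46,
            f"architecture        {spec.arch}"
            + (" + embeddings" if spec.use_chemberta else ""),
            f"labels              {spec.n_labels}",
            f"conv layers         {spec.n_conv_layers}" if spec.is_graph else
            "linear layers       3",
            f"node features       {spec.node_feature_dim}",
            f"hidden dim          {spec.hidden_dim}",
            f"parameters          {n_params}",
            f"epochs              {spec.epochs}",
            f"learning rate       {spec.lr}",
            f"weight decay        {spec.weight_decay}",
            f"decision threshold  {spec.decision_threshold}",
            f"final BCE loss      {self.training_log[-1]:.6f}",
            f"fit time            {self.fit_seconds:.1f} s",
            "-" * 46,
            "labels: " + ", ".join(self.label_ids),
        ]
        return "\n".join(lines)

    # ----------------------------------------------------------- persistence
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "spec.json").write_text(json.dumps(asdict(self.spec), indent=2))
        (out / "labels.json").write_text(json.dumps(self.label_ids))
        (out / "vocab.json").write_text(
            json.dumps(self.model.dataset.vocab.to_json_dict()))
        (out / "scaler.json").write_text(
            json.dumps(self.model.dataset.scaler.to_json_dict()))
        (out / "weights.json").write_text(json.dumps({
            "training_log": self.training_log,
            "arrays": [p.tolist() for p in self.params],
        }))

    @classmethod
    def load(cls, in_dir, dataset: FeaturizedDataset) -> "FunctionPredictionResults":
        path = Path(in_dir)
        spec = ModelSpec(**json.loads((path / "spec.json").read_text()))
        model = MetaboliteFunctionModel(dataset, spec)
        net = model._build_net(np.random.default_rng(spec.seed))
        blob = json.loads((path / "weights.json").read_text())
        net.load_state_arrays([np.asarray(a) for a in blob["arrays"]])
        return cls(model, net, blob["training_log"])
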