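# metabofunc

Structure-based prediction of metabolite functions with graph neural
networks.

Most small molecules detected in metabolomics experiments carry few or no
functional annotations. `metabofunc` asks how far function can be predicted
from structure alone: given HMDB-style records — a SMILES structure, a
detection status, and annotations in a functional ontology rooted at four
categories (*Disposition*, *Role*, *Process*, *Physiological effect*) — it
trains multilabel classifiers that output one binary decision per selected
ontology term, and explains the graph-attention model's decisions at the
level of individual chemical bonds.

The package is aimed at computational metabolomics and cheminformatics
researchers who want a complete, reproducible pipeline: ingestion,
statistical label filtering, leakage-aware splitting, graph featurization,
model training/comparison, and attention-based interpretability — all
runnable offline on a single CPU.

## The method

**Term selection.** Most ontology terms are annotated for almost no
metabolite and carry no learnable signal. For each term *j* the per-term
standard deviation over the binary annotations x<sub>ij</sub> of the
detected-and-quantified metabolites is

σ<sub>j</sub> = √( Σ<sub>i</sub> (x<sub>ij</sub> − x̄<sub>j</sub>)² / (N − 1) ),

and terms are kept when the modified Z-score of their σ against the
median/MAD of all leaf-term σ's,

M<sub>i</sub> = 0.6745 · (s<sub>i</sub> − s̃) / MAD,

satisfies |M<sub>i</sub>| > 3.5. Only leaf (childless) terms of one
category are candidates.

**Models.** Each metabolite becomes a graph (one node per heavy atom, one
edge per bond in both directions). Node features are the one-hot element
identity over the dataset vocabulary (N×M) plus two standardized 2D
coordinate columns (N×(M+2)); edge features one-hot the bond type. Five
architectures share one training recipe (Adam, binary cross-entropy, 2
convolution layers, 64 node features, 32 hidden units, 20 epochs, learning
rate 0.005, weight decay 0.001, decision threshold 0.5):

| variant | input | core |
|---|---|---|
| GCN / GIN / GAT | molecular graph | 2 graph convolutions → sum pooling → FC |
| GCNC / GINC / GATC | graph + molecule embedding (600-d, mean-pooled SMILES transformer) | embedding concatenated before the FC layer |
| Baseline (MLP) | 1024-bit Morgan fingerprint | 3 linear layers |
| MLP (embedding) | 600-d molecule embedding | 3 linear layers |

The GAT uses 8 attention heads and consumes bond-type edge features.
Train/test splitting clusters metabolites by identical selected-label
vectors and splits every cluster 0.9/0.1, so each label appears on both
sides; model comparison uses five-fold cross-validation over the training
portion.

**Interpretability.** For the GAT, the per-head attention coefficients of a
chosen layer are captured during a forward pass; each bond receives the
maximum weight across heads (directions merged by max), min-max scaled
within the molecule. A substructure-enrichment statistic with a
permuted-weight null quantifies whether attention concentrates on a given
fragment.

The neural networks, the Adam optimizer and backpropagation are implemented
in-repo on a small NumPy reverse-mode autodiff engine
(`metabofunc.autograd`, `metabofunc.nn`), gradient-checked against finite
differences; runs are seeded and bit-reproducible on CPU.

## Worked example

The synthetic-data module generates HMDB-style datasets in which ontology
terms are planted on chemical motifs (carboxyl, sulfonamide, phenyl, ...),
with 5% label noise and a background of rare uninformative terms — so every
stage has known ground truth:

```python
import warnings
from metabofunc import ModelSpec, MetaboliteFunctionModel, featurize_dataset
from metabofunc.datatypes import DetectionStatus
from metabofunc.evaluation import compute_metrics
from metabofunc.label_selection import select_labels
from metabofunc.splitting import cluster_by_output, split_clusters
from metabofunc.synthetic import FixtureSpec, generate_dataset

ds = generate_dataset(FixtureSpec(n_molecules=1000, seed=0,
    status_mix={DetectionStatus.detected_quantified: 1.0}))
table = ds.truth_table()
selection = select_labels(table, ds.tree, category="Process")
print("selected Process terms:", selection.selected)

labels = ds.motif_term_ids
clusters = cluster_by_output(table, labels)
plan = split_clusters(clusters, ratio=0.9, seed=0, table=table, selected=labels)
data = featurize_dataset(ds.records, table, labels, fit_ids=plan.train_ids)

model = MetaboliteFunctionModel(data.subset(plan.train_ids),
                                ModelSpec(arch="gat", n_labels=len(labels), seed=0))
results = model.fit()
print(results.summary())

test = data.subset(plan.test_ids)
probs, binary = results.predict(test)
report = compute_metrics(test.labels, probs, label_ids=labels)
print(f"held-out macro F1 = {report.macro_f1:.3f}, AUPRC = {report.auprc_macro:.3f}")
```

Output:

```
selected Process terms: ['noise-38', 't-carboxyl', 't-phenyl']
Metabolite function prediction results
==============================================
architecture        gat
labels              8
conv layers         2
node features       64
hidden dim          32
parameters          86696
epochs              20
learning rate       0.005
weight decay        0.001
decision threshold  0.5
final BCE loss      0.239998
fit time            35.9 s
----------------------------------------------
labels: t-carboxyl, t-phenyl, t-sulfonamide, t-morpholine, t-trifluoromethyl, t-phosphate, t-nitrile, t-pyridyl
held-out macro F1 = 0.937, AUPRC = 0.938
```

The dispersion filter recovers the two motif terms planted under *Process*
(it also picks up the one mid-prevalence random term — outlier selection is
purely statistical, and an outlier need not be learnable). The GAT then
recovers the planted structure→function rules on held-out molecules with a
macro F1 close to the ceiling imposed by the 5% label noise.

A command-line interface mirrors the stages
(`metabofunc synth | ingest | filter-labels | split | run`); a full
config-driven run writes every stage artifact plus a JSON-lines log into
its output directory and is byte-reproducible given the same config and
seed.

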