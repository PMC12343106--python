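# Methods

This note documents the modelling choices, defaults and known limitations
of `metabofunc`, in the spirit of a model-description appendix.

## Data model and ingestion

A metabolite record carries an id, a SMILES structure, one of four
detection statuses (`expected`, `predicted`, `detected_not_quantified`,
`detected_quantified`) and a set of ontology-term annotations. The ontology
is a forest rooted at the four functional categories (Disposition, Role,
Process, Physiological effect). Only detected-and-quantified metabolites
are modeled: in the other status groups almost no annotation information
exists, so nearly all terms have near-zero dispersion there (the package
exposes `per_status_std_report` to reproduce this comparison; it plays no
role in selection).

The XML dialect is a documented subset of the HMDB metabolite export
(`metabolite`/`accession`/`smiles`/`status`/`ontology` with nested
`root`/`descendant`/`term` elements). The writer emits the same dialect,
so synthetic datasets exercise the identical parser. Annotations are
written ancestor-closed (as real exports list full paths); consequently
`parse(write(x))` returns the ancestor closure of `x`'s annotations.

2D coordinates come from per-metabolite SDF/MOL files when present; they
are reordered to the SMILES parser's atom order by substructure matching.
Missing or mismatched files fall back to a computed 2D layout (flagged and
counted) — the pipeline must not die on incomplete structure archives.
Hydrogens are implicit throughout; only heavy atoms become graph nodes.

Annotation propagation to ancestors is off by default: models predict the
terms exactly as annotated, restricted to leaf terms. A `propagate` toggle
exists for ontologies where an annotation at a child should imply the
parent.

## Term selection

Candidate outputs are the childless descendants of one category root. For
each candidate, the sample standard deviation of its binary annotation
column is computed; for a binary column with k positives out of N this is
exactly √(k(N−k)/(N(N−1))), which is how it is evaluated (order-insensitive
and bit-reproducible — relevant because the downstream MAD compares sigmas
for exact ties). Modified Z-scores M = 0.6745·(s − median)/MAD over the
candidate sigmas are thresholded at |M| > 3.5, strictly.

Numerical/degenerate policies:

* MAD = 0 (at least half the candidate sigmas identical, e.g. many
  never-annotated terms on a small dataset) raises a hard error; no silent
  fallback. Small datasets genuinely do not support this selection rule.
* The absolute-value rule also selects the *low*-sigma tail, which is
  uninformative; selections report how many terms came from each tail so
  this can be audited. The rule is kept as stated rather than one-sided.
* The median of an even-length vector is the mean of the two central
  values.
* A category root without children yields an empty candidate list with a
  warning; a root is never treated as its own leaf.
* Truth tables default to one column per ontology term, including terms
  with zero annotations: the all-zero columns are real (zero-dispersion)
  data for the selection statistic, matching the shape of a full ontology.

## Splitting

Metabolites with identical selected-label vectors form clusters; every
cluster of size ≥ 2 sends max(1, round(0.1·size)) members (half-up
rounding) to the test side under a seeded shuffle. Singleton clusters go
entirely to train — their label combination cannot be represented on both
sides, and a label seen once must at least be trainable; this is logged.
The guarantee "every selected label occurs on both sides" is checked post
hoc for labels carried by at least one cluster of size ≥ 2 and violations
are reported on the plan. Exact-vector equality was chosen over
distance-based clustering as the simplest rule that delivers the
representation guarantee. Cross-validation folds are dealt round-robin
within each shuffled cluster (with a rotating starting fold); CV operates
on the training portion only, leaving the 10% holdout untouched.

## Featurization

Node features: one-hot element identity over the dataset vocabulary
(elements sorted by atomic number; optional trailing unknown slot), plus
two coordinate columns unless ablated. "Normalized and standardized"
coordinates are implemented as per-molecule centering and max-abs scaling
followed by per-axis z-scoring fitted on the training molecules only (no
test leakage; single-atom molecules map to the origin; a zero-spread axis
passes through with a warning). The per-molecule step keeps raw drawing
units from dominating the one-hot block. Whether the standardization
should instead be global is genuinely open; the scheme is a config point
(`fit_ids`) rather than a hidden constant.

Edges: both directions of every bond, with a 4-way one-hot bond type
(single/double/triple/aromatic; anything rarer maps to single). Bond-type
features are built for all architectures but consumed only by the GAT,
whose attention score includes a learned projection of the edge feature;
GCN and GIN have no mechanism for edge features and ignore them.

Baseline input: 1024-bit Morgan fingerprint, radius 2 (the radius is a
gap-filling choice; only the length is fixed by design), computed by RDKit
and hence invariant to SMILES spelling.

## Embeddings

The production backend mean-pools per-token hidden vectors (last hidden
layer by default; configurable) of a pretrained ChemBERTa-style SMILES
transformer, dimension 600, excluding padding/special tokens from the mean
— special tokens are not parts of the SMILES. The transformer stack is an
optional dependency; the default backend is a deterministic stub producing
a unit-norm pseudo-random vector keyed by the canonical SMILES, so the
pipeline and its tests run offline. The stub acts as a per-molecule
identity feature: useful for exercising the fusion path, carrying no
chemical generalization. Batch embedding caches by canonical SMILES in a
versioned JSON file; corrupt caches are rebuilt with a warning.

## Architectures and training

All models end in a fully connected layer producing one logit per selected
term, through a logistic output. Graph models: linear projection of node
features to 64 dimensions, two convolution layers of the chosen family
(hidden dimension 32), ReLU between layers, sum-aggregation readout, then
optionally the 600-d molecule embedding concatenated before the FC layer.
The GAT uses 8 heads, concatenating head outputs after layer 1 (width
8·32) and averaging heads at layer 2 — standard practice where the design
was open. MLPs are three linear layers, input → 128 → 32 → labels (hidden
widths are gap-filling choices).

Training: Adam (learning rate 0.005, weight decay 0.001 as L2 folded into
the gradient), mean binary cross-entropy on logits, 20 epochs, batch size
32 (unstated in the original design; logged), no early stopping and no
validation split — model selection happens in cross-validation. BCE is
unweighted; class imbalance is handled at the metric level. All randomness
(initialization, batch order) derives from the spec seed; single-threaded
NumPy runs are bit-reproducible. A non-finite loss aborts with the epoch,
batch and learning rate in the message.

Decisions are strict: a probability exactly at the threshold is negative.

## Evaluation

Per-label precision/recall/F1 at the 0.5 threshold with a zero-division
policy of 0 (warned); macro = unweighted mean, weighted F1 weights by
positive support. Average precision uses the step-wise rectangle rule on
the PR curve (per label, macro-averaged; per-label values retained).
Labels with no positives in the evaluated fold score 0 with a warning.
Cross-validated comparison trains every spec on identical folds and
reports mean ± sd per metric; ablations train matched pairs (identical
folds and seeds) and report entrywise deltas — coordinates change the
node-feature width from N×(M+2) to N×M, the embedding ablation shrinks the
FC input by 600.

## Interpretability

Attention attribution defaults to layer 1 (closest to the atomic input;
configurable). Per directed edge, the maximum over the 8 heads is taken;
the two directions of a bond are merged by max (not mean), then min-max
scaled per molecule. Merge-then-scale ordering is a documented choice. A
molecule whose raw weights are all equal — including single-bond molecules
— gets every scaled weight set to 1.0 and a degeneracy flag, rather than 0
or NaN. Enrichment compares mean scaled weight on bonds inside a matched
substructure vs outside, per molecule; the permutation null shuffles each
molecule's bond weights and recomputes the inside>outside fraction
(add-one-corrected empirical p).

## Synthetic data

The generator decorates random alkyl chains (4–9 carbons) with up to eight
chemically distinct motif fragments, each attached independently with
probability 0.4; a molecule carries a motif's ontology term exactly when
it contains the motif by substructure match (construction-independent
ground truth), then labels are flipped with rate 0.05. Forty additional
structureless terms are assigned at random: most at 0.1–1% prevalence,
four at 5–30%. This prevalence profile is what dispersion-based selection
needs to behave as it does on a real ontology, where never-annotated terms
dominate: the rare mass pins the median and MAD of the sigma vector low,
making genuinely informative terms extreme outliers, while the
mid-prevalence terms are structureless columns that can land on either
side of the threshold. The default status mix is 70% detected-and-
quantified, 10% each of the other three.

What the generator does *not* emulate: realistic metabolite chemistry
(ring systems, stereochemistry, charge states), correlated labels,
annotation sparsity that depends on molecule family, or systematic
annotation bias. Passing tests on this fixture demonstrate that the
machinery learns planted structure→function rules and that attention
localizes on the responsible substructure — not that real HMDB-scale
performance figures are reproduced, which depend on a specific database
release (see `docs/hmdb_reproduction.md`).

Problem sizes used by the test-suite and acceptance script: 1000 molecules
for the learnability/enrichment runs, 80–300 for pipeline and unit-level
checks. With 5% symmetric label noise and 40% prevalence, a perfect
predictor's expected per-label F1 is ≈ 0.94, which bounds achievable macro
F1 on noisy held-out labels.

## Known limitations

* Held-out macro F1 of the GAT varies by a few points across generator
  and training seeds at n = 1000 (≈ 0.87–0.94 observed); the fixed 20-epoch
  recipe has no early stopping or model selection, so some runs underfit
  individual labels. The fingerprint baseline is more stable on this task
  because radius-2 Morgan bits encode the planted fragments almost
  directly.
* Attention enrichment is strong for chain-attached motifs (carboxyl,
  sulfonamide) but inverts for ring motifs (phenyl): softmax attention per
  destination node is inversely related to degree, so densely bonded ring
  atoms receive systematically lower per-edge weights. Bond-level
  attention should not be read as a degree-corrected importance measure.
* MAD selection is unreliable below a few hundred metabolites (MAD can be
  exactly zero); this is inherent to the rule, not guarded away.
* The deterministic stub embedding cannot transfer chemical knowledge;
  conclusions about embedding fusion on synthetic data concern the
  plumbing, not pretrained-representation quality.
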