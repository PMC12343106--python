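# Applying the pipeline to a real HMDB export

Results on real data depend on the specific HMDB release (term inventory,
annotation coverage and detection statuses all change between releases),
so this is a manual protocol, not part of the automated test suite.

1. **Download** the "All Metabolites" XML export and the structures
   (SDF) archive from the HMDB download page. Unpack the SDF archive into
   a directory of per-metabolite `<accession>.sdf` files (or keep the
   combined SDF and split it; the parser expects one file per id).

2. **Adapt the schema if needed.** `metabofunc.ingest.parse_hmdb_xml`
   reads the fixture dialect (`metabolite`/`accession`/`smiles`/`status`/
   `ontology` with nested `root`/`descendant`/`term`). Recent HMDB
   releases use the same element names inside a namespaced document;
   strip the namespace (e.g. with a one-line XSLT or `sed`) or extend the
   parser's tag lookup. Map the release's detection-status strings onto
   the four canonical values (`DetectionStatus.parse` already accepts the
   common spellings).

3. **Ingest and filter:**

   ```bash
   metabofunc ingest --xml hmdb_metabolites.xml --sdf-dir structures/ --out work/
   metabofunc filter-labels --table work/truth_table.tsv \
       --tree work/ontology.json --category Process --out work/selection.json
   ```

   Restrict the truth table to detected-and-quantified metabolites before
   selection (the `run` pipeline does this automatically). Expect on the
   order of 10–30 selected leaf terms per category on a full release.

4. **Split, train, compare:**

   ```bash
   metabofunc split --table work/truth_table.tsv --selection work/selection.json \
       --ratio 0.9 --seed 7 --folds 5 --out work/plan.json
   metabofunc run --config run.yaml   # per-category configs; evaluation: cv
   ```

   Train one model per category; compare the eight variants
   (GCN/GIN/GAT ± embeddings, fingerprint baseline, embedding MLP) with
   `metabofunc.evaluation.cross_validate` under identical folds.

5. **Embeddings.** For real runs install `transformers` and configure
   `EmbeddingProvider(backend="pretrained_transformer")` with a
   ChemBERTa-style checkpoint (hidden size must equal the configured
   dimension, 600 by default). The offline stub is not a substitute for
   pretrained embeddings on real data.

6. **Interpretability.** Explain held-out molecules of a family of
   interest (e.g. a lipid class for a membrane-localization label) with
   `metabofunc explain`, and quantify substructure focus with
   `substructure_enrichment` using a SMARTS pattern for the family's
   head group.

Expect full-release numbers to differ from any published figures unless
the identical release, filtering and split seed are used; counts such as
"terms selected per category" are sensitive to the release's annotation
coverage.
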