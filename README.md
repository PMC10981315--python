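# daecfr

Prediction of miRNA–disease associations from a known-association catalog by
integrating Gaussian interaction-profile (GIP) kernel similarity, miRNA
functional similarity and hierarchy-based disease semantic similarity;
sharpening the integrated similarities with a logistic contrast transform;
balancing classes with k-means negative sampling; compressing four feature
views with small deep autoencoders; and scoring pairs with a logistic
regression classifier under stratified k-fold cross-validation.

## Layout

| module | role |
| --- | --- |
| `daecfr.data_io` | readers/writers (association lists, similarity matrices, tree-number maps, rankings) and run configuration |
| `daecfr.similarity` | GIP kernels, disease DAG forest, two semantic similarity models + mean, integration, logistic transform |
| `daecfr.sampling` | pair universe, k-means negative sampling, training-set assembly |
| `daecfr.encoding` | feature views, NumPy deep autoencoder, latent pair features |
| `daecfr.evaluate` | classifier, metrics (AUC/AUPR/F1/ACC/MCC), k-fold CV, grid search, repeats, ablation, case-study ranking |
| `daecfr.fixtures` | synthetic planted/null datasets and hand-computed DAG oracle cases |

## Inputs

* **Association list** — two-column TSV `miRNA-id<TAB>disease-id`
  (optional header, duplicates collapsed).
* **Functional similarity** — square TSV with matching row/column identifier
  headers; identifiers missing from the file fall back to kernel-only
  integration.
* **Disease hierarchy** — two-column TSV `disease-id<TAB>tree-number`
  (e.g. `C14.280.647`); dot-prefixes are ancestors.

All three are optional except the association list; without functional or
hierarchy inputs the pipeline degrades gracefully to GIP-kernel-only
similarity, as the integration rule prescribes.

## CLI

```bash
daecfr simulate --n-m 200 --n-d 150 --seed 1 --out-dir fixtures/
daecfr similarity --assoc fixtures/associations.tsv --fm fixtures/fm.tsv \
    --mesh fixtures/tree_numbers.tsv --c -8 --out-dir sims/
daecfr sample --assoc fixtures/associations.tsv --k 23 --per-cluster 240 \
    --seed 7 --out training.tsv
daecfr encode --assoc fixtures/associations.tsv -L 8 --epochs 100 \
    --seed 7 --out-dir latents/
daecfr cv --assoc fixtures/associations.tsv --fm fixtures/fm.tsv \
    --mesh fixtures/tree_numbers.tsv --folds 5 --repeats 10 --out metrics.tsv
daecfr grid --assoc fixtures/associations.tsv --c-min -15 --c-max -1 -L 8,16,32,64
daecfr rank --assoc fixtures/associations.tsv --disease d0005 --top 10
```

Run parameters can also come from a flat `key = value` config file
(`--config run.cfg`); defaults are `c = -8`, `L = 8`, `k_clusters = 23`,
`per_cluster = 240`, `folds = 5`, `batch_size = 100`.

## Notes

* The deep autoencoder is implemented in NumPy (symmetric
  `[D, 256, L, 256, D]`, ReLU/sigmoid, MSE, Adam, batch 100) — exact
  seed-determinism, no framework dependency.
* By default similarities and feature views are computed once from the full
  association matrix before fold splitting, mirroring the published
  protocol; `leakage_safe = true` recomputes kernels, views and
  autoencoders per fold with test-fold positives zeroed.
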