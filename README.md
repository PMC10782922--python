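# cofea

Correlation-based feature selection for single-cell chromatin accessibility
(scATAC-seq) peak-by-cell count matrices, with a synthetic-data generator,
baseline selectors, and a clustering-based evaluation harness.

## Method

Given a peak-by-cell count matrix, the selector:

1. removes peaks detected in fewer than 1% of cells (inclusive threshold);
2. applies a TF-IDF transformation
   (`signac` default: `x' = log(1 + (x/colsum) * (n/rowsum) * 1e4)`,
   natural log; `origin` and `scopen` variants available);
3. runs *cell-wise* PCA — peaks are observations, cells are centered
   variables — producing a peak-by-PC embedding (100 components default);
4. summarizes each peak by the mean and mean-square of its correlation
   coefficients (Pearson by default; Spearman / cosine available) against
   all other peaks. The peak-by-peak matrix is never materialized: rows are
   standardized once and processed in blocks, so memory scales with
   `p*q + chunk_size*p`, never `p^2`. Results are independent of chunk size
   and worker count;
5. fits a LOWESS curve of mean-square vs mean three times, trimming points
   outside the [5%, 95%] normal-residual quantiles between fits, and scores
   every peak by its absolute residual from the final curve;
6. returns the top-k peaks by score (ties broken by original index).

Peaks that behave like the background follow the fitted trend; peaks
specific to a cell subpopulation have unusually high mean-square
correlation for their mean and stand out as outliers.

## CLI

```bash
# generate a synthetic dataset with planted type-specific peaks
cofea simulate --archetype S4 --seed 0 --out-dir sim/

# rank peaks and select the top 800
cofea select --mtx sim/matrix.mtx --bed sim/peaks.bed \
    --barcodes sim/barcodes.tsv --n-features 800 \
    --n-pcs 100 --tfidf signac --corr pcc --seed 0 --out scores.tsv

# benchmark against the baselines on re-simulations of the same spec
cofea evaluate --sim-dir sim/ --methods cofea,hda,signac,episcanpy \
    --n-features 800 --seeds 0,1,2,3,4 --out report.tsv
```

Every command writes a JSON manifest beside its outputs (resolved
configuration, SHA-256 input/output digests, library versions).
`cofea select --config run.cfg` reads a flat `key=value` file; CLI flags
take precedence over it.

File formats: Matrix Market coordinate integer counts (1-based triplets),
BED3 peaks (0-based half-open), one barcode per line, optional
`barcode<TAB>label` TSV. Score tables are TSV with columns
`peak_index` (0-based original row), `peak_id` (`chrom:start-end`),
`score`, `rank` (1 = most significant), `selected`.

Simulation archetypes: `S1` uniform accessibility, `S2`/`S3` dynamic
(wider) per-peak accessibility ranges, `S4` rare cell type, `S5`
three-branch differentiation trajectory. Ground truth is written to
`truth.tsv` and the resolved spec to `spec.json`.

## Evaluation harness

`cofea.evaluation` provides: `overlap_proportion` (denominator
`min(|selected|, |truth|)`), the `hda` / `signac` / `episcanpy` baseline
selectors (the latter two approximate the published tools' feature-selection
steps only), and `cluster_and_score` — TF-IDF, 50-component PCA over cells,
cosine kNN graph, Leiden with the resolution binary-searched to the true
type count, reporting NMI / AMI / ARI / homogeneity / scaled silhouette
(ASW) / cLISI.

## Python API

```python
from cofea import SimulationSpec, simulate, run_cofea, overlap_proportion

ds = simulate(SimulationSpec.default("S1", seed=0))
table = run_cofea(ds.counts, k=800, seed=0)
print(overlap_proportion(table.selected_set(), ds.specific_set))
```
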