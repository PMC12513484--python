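# orgspatial

Spatial single-cell analysis for imaging-based transcriptomics of cortical
organoid sections: marker-exclusive cell typing, cross-type distance
distributions, neighborhood-density statistics, rank-based differential
expression, composition tests, and the accompanying bench-assay
quantitations (relative qPCR by 2^−ΔΔCt, deiodinase fractional-conversion
activity).

## Who this is for

Groups profiling organoid or tissue sections on an imaging platform
(CosMx-style "flatfile" CSV exports: a cells × genes count table plus
per-cell centroid/metadata table) who want the downstream statistics as a
reproducible, scriptable pipeline rather than a notebook: how are the
marker-defined populations arranged in space, does local cell density
associate with expression, and which genes shift between conditions
(e.g. control vs MCT8-deficient organoids)?

## The statistics at the core

- **QC and normalization.** Cells with > 15 genes detected and > 20
  transcripts are kept (a deliberately relaxed filter for shallow imaging
  panels); expression is library-size normalized over all panel genes,
  `x_cg = ln(1 + c_cg · 10⁴ / Σ_g c_cg)`.
- **Exclusive marker typing.** A cell is type *T* iff it expresses at
  least one marker of *T* (raw count ≥ 1) and none of any other type's
  markers; all other cells are `undefined`. The default panel identifies
  NPCs (VIM, NOTCH1, BMP7), IPCs (EOMES, BMP5) and neurons (GATA3, DCN,
  SPOCK2, SOX4).
- **Distances and KS.** All Euclidean distances between cells of two
  types, per section, aggregated by condition; conditions are compared
  with the two-sample Kolmogorov–Smirnov statistic
  `D = sup |ECDF₁ − ECDF₂|`.
- **Neighborhood metric.** `n(c)` = number of cells (any type) within
  100 μm of cell *c* in its own section. `n = 1` defines *sparse* cells,
  `n ≥ 5` *dense* cells, anything else intermediate. Association with
  expression is tested per cell-type group by OLS of expression on `n`
  (t-test on the slope) and by logistic regression of dense-vs-sparse on
  expression (Wald test), each BH-adjusted across genes.
- **Differential expression.** Two-sided Wilcoxon rank-sum per gene
  between conditions within each group, Seurat-style
  `avg_log2FC = log₂((mean(expm1 x_A)+1)/(mean(expm1 x_B)+1))`, BH-FDR;
  selection presets: adjusted p < 0.05 with no fold-change floor
  (imaging panel) or |log2FC| ≥ 0.26 (split-pool scRNA).
- **Composition.** Pearson χ² (no continuity correction) on the cell-type
  × condition table, overall and per type (type vs rest), BH-adjusted.

A seeded synthetic-data generator (`orgspatial.simulate`) emulates the
whole input: Poisson background + Thomas-cluster layouts (so sparse and
dense neighborhoods both occur), three marker-defined types plus
undefined cells, and negative-binomial counts with planted condition and
density effects, with the ground truth returned alongside the dataset.

## Worked example

```python
import orgspatial as osp
from orgspatial.simulate import fixture_small

ds, truth = fixture_small()                      # ~400 cells, 60 genes, known truth
ds_qc, report = osp.filter_cells_spatial(ds)
expr = osp.lognormalize(ds_qc)
labels = osp.assign_cell_types(ds_qc, osp.MarkerPanel())

profile = osp.neighborhood_metric(ds_qc, r=100)
d = osp.pairwise_type_distances(ds_qc.with_cell_types(labels), "NPC", "neuron")

m = labels == "NPC"
res = osp.wilcoxon_de(expr.values[m & (ds_qc.condition == "MCT8")],
                      expr.values[m & (ds_qc.condition == "control")],
                      gene_ids=expr.gene_ids)
sig, counts = osp.select_degs(res, preset="spatial_nofc")
```

This prints (via the obvious `print` calls):

```
345 cells simulated, 344 pass QC
sparse: 55 dense: 146
KS D = 0.064, p = 6.42e-03
NPC DE genes: ['DEG_A', 'DEG_C', 'DEG_D'] {'up': 2, 'down': 1, 'total': 3}
```

344 of 345 simulated cells clear the relaxed QC; 55 cells sit in sparse
and 146 in dense neighborhoods; the NPC–neuron distance distributions
differ modestly but significantly between genotypes (D = 0.064); and the
NPC group recovers three of the four planted condition-effect genes
(`DEG_B` is recovered in another group — the planted effect applies to
every cell, and each group is tested separately).

The same run end-to-end, from a shell:

```sh
orgspatial simulate --seed 7 --out data/
orgspatial run --counts data/counts.csv --meta data/metadata.csv --out results/
```

which writes the QC report, annotation summary, distance/KS table,
neighborhood profile, density-association tables, DE table, composition
tests and a `manifest.json` with a SHA-256 digest per table (re-running
the same config and seed reproduces every table byte-for-byte).

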