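# tcellproj

Reference-atlas projection for T-cell scRNA-seq data.

Single-cell studies of T cells describe the same biology — naive-like,
effector-memory, precursor-exhausted (Tpex), terminally exhausted (Tex),
regulatory and helper states — with study-specific cluster labels that cannot
be compared across papers, tissues or species. `tcellproj` addresses this by
(i) building an integrated, annotated **reference atlas** of T-cell states
from multiple scRNA-seq datasets and (ii) **projecting** new query datasets
into the atlas's frozen coordinate spaces, so that every experiment is
interpreted on the same map. The reference is never altered by a projection:
any number of conditions (knock-out vs wild-type, tissues, patients, even
human data mapped through mouse orthologs) can be compared on identical
coordinates.

## The method

**Normalization.** Raw UMI counts `x` in a cell with total count `S` are
log-normalized as `ln(1 + 10^4 · x / S)`.

**Integration (atlas building).** Each dataset contributes its top 600
variable genes (loess-standardized variance, excluding cycling, mitochondrial,
ribosomal and non-coding genes and genes detected in <0.1% or >90% of cells);
a consensus of 800 genes prioritizes genes variable in many datasets. Batches
are linked by **anchors** — mutual nearest neighbor cell pairs in reciprocal
PCA spaces — scored by neighborhood consistency and reciprocal-space
proximity, and filtered at a score threshold of 0.8. Each cell receives a
correction vector, the Gaussian-kernel weighted average of its nearest
anchors' (reference − query) expression differences.

**Frozen reductions.** On the integrated matrix the atlas freezes: gene
centering/scaling, a 50-component PCA rotation, a fitted UMAP transform, and
a 50-component ICA rotation (whitened fixed-point ICA; each component reads
as a gene program). Functional clusters come from shared-nearest-neighbor
Louvain clustering (resolution 0.6, k = 20 on the UMAP embedding by default)
and are annotated from marker signatures.

**Projection and classification.** A query is normalized, optionally
T-cell-filtered and ortholog-mapped, batch-corrected *toward* the atlas, and
passed through the frozen rotations and the UMAP transform. Each query cell's
subtype is the majority vote of its k = 20 nearest annotated reference cells
in PCA space, with the vote fraction as confidence.

**Perturbation analysis.** Conditions are compared by subtype composition and
fold changes, by per-dimension two-sample Kolmogorov–Smirnov tests on the ICA
coordinates (Bonferroni ×50) to find **discriminant gene programs**, and by
Wilcoxon rank-sum differential expression within a subtype. TCR clonal
structure is linked to subtypes via the Morisita overlap index and
clonotype-enrichment rules.

## Worked example

Build an atlas from five simulated datasets and project the sixth as a query
(the packaged simulator produces six negative-binomial datasets with five
T-cell-like subtypes, batch effects, and known truth):

```python
from tcellproj import SimulationConfig, generate_synthetic_atlas_inputs, project
from tcellproj.atlas import AtlasBuilder, annotate_clusters
from tcellproj.interpret import subtype_composition
from tcellproj.simulate import marker_genes_of

cfg = SimulationConfig()                       # 6 datasets, 5 subtypes, seed 42
datasets, truth = generate_synthetic_atlas_inputs(cfg)

builder = AtlasBuilder(random_state=0)
atlas = builder.fit(datasets[:5]).atlas_       # hold out dataset 5 as the query
signatures = {f"S{k}": marker_genes_of(cfg, k) for k in range(cfg.n_subtypes)}
atlas.labels = annotate_clusters(atlas, signatures)
atlas.subtype_order = sorted(set(atlas.labels))

result = project(datasets[5], atlas, filter=False)
comp = subtype_composition({"query": result.predicted_label})
print(comp.to_string(index=False))

acc = (result.predicted_label.values
       == truth.loc[result.query.cell_ids, "true_subtype"].values).mean()
print(f"agreement with simulated truth: {acc:.1%}")
print(f"mean label confidence: {result.label_confidence.mean():.2f}")
```

This prints:

```
subtype condition  count  fraction
     S0     query     55  0.183333
     S1     query     61  0.203333
     S2     query     79  0.263333
     S3     query     49  0.163333
     S4     query     56  0.186667
agreement with simulated truth: 92.3%
mean label confidence: 0.75
```

The composition table is the per-subtype breakdown of the projected query
(fractions sum to 1); 92.3% of the query cells are assigned the subtype they
were simulated from, and the mean confidence is the average fraction of
agreeing neighbors in the k = 20 vote.

The same pipeline is available from the shell:

```bash
tcellproj simulate --seed 42 --out sim/
tcellproj build-atlas --config atlas.yml --out atlas/
tcellproj project --atlas atlas/ --query sim/dataset5 --out proj/
```

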