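# gepcat

Consensus gene-expression-program (GEP) catalogs and fixed-catalog
projection for single-cell RNA-seq and CITE-seq data.

## The problem

Single-cell transcriptomes are additive mixtures of co-regulated gene
modules: identity programs that define a cell's subset (naive CD4, Treg,
MAIT, ...) and activity programs (activation, cell cycle, interferon
response) that overlay them. Nonnegative matrix factorization decomposes a
cell-by-gene matrix into such programs, but a factorization learned on one
dataset does not transfer to the next, and small datasets cannot support a
stable factorization at all.

`gepcat` implements the full stack around a fixed program catalog:

1. **Consensus NMF per dataset.** NMF is run many times on the
   batch-corrected, unit-variance matrix of overdispersed genes,

   argmin over U ≥ 0, G ≥ 0 of ‖X − U·G‖_F,

   replicate spectra are density-filtered, k-means clustered, and the
   cluster medians become robust spectra G; usages U are refit by
   nonnegative least squares, and spectra are re-expressed over all genes
   (and ADT proteins) in TPM and z-score units.
2. **Cross-dataset merging.** Dataset-level GEPs become nodes of a graph
   with edges between cross-dataset pairs with Pearson R > 0.5 that are
   mutually within each other's top-7 correlations; edges are replayed in
   decreasing R and sets merged greedily whenever at least two-thirds of
   all node pairs in the merged set are connected. Element-wise averages of
   merged sets form the consensus catalog (cGEPs).
3. **Fixed-catalog projection.** A new dataset is annotated per cell by
   solving, with the catalog G\* held fixed,

   argmin over U ≥ 0 of ‖X_query − U·G\*‖_F,

   on SD-normalized query counts; usages are row-normalized to sum to one.
   Derived per-cell scores are linear functionals of usage: an
   antigen-specific activation (ASA) score (positive above 0.0625), a
   cell-cycle score (proliferating above 0.1), doublet flags, and subset
   labels from a balanced multinomial logistic classifier.
4. **A gamma-Poisson simulator** (`scsim2`) in which every cell expresses
   one subset GEP plus a random set of additive activity GEPs with capped
   total usage — the ground-truth testbed for all of the above.
5. **Downstream statistics**: pseudobulk OLS associations with BH FDR,
   paired proliferation tests with Fisher-method meta-analysis, greedy
   AUC-driven forward selection of ASA components, and Fisher-exact marker
   gene-set enrichment.

The fit/transform cores follow scikit-learn conventions (`ConsensusNMF`,
`CatalogProjector`, `HarmonyCorrector`, `SubsetClassifier`, `ADTSmoother`)
and compose with sklearn pipelines; module-level functions wrap them.

## Worked example

Simulate a small dataset, learn a consensus factorization, and project a
fresh query onto it:

```python
import numpy as np, pandas as pd
from gepcat import (SimParams, simulate_dataset, filter_counts,
                    select_overdispersed, build_xraw, fit_usage)
from gepcat.cnmf import ConsensusNMF
from gepcat.data_model import GEPCatalog

params = SimParams(n_genes=3000, n_subset_geps=4, n_activity_geps=2, seed=0)
counts, truth = simulate_dataset(1500, params, np.random.default_rng(0))
# -> 1500 cells x 3000 genes, median depth 2138 UMIs

filtered = filter_counts(counts)            # >=10 cells/gene, >=500 UMIs/cell
genes = select_overdispersed(filtered, n_genes=500)
xraw = build_xraw(filtered, genes)          # unit-variance counts, ceiling
model = ConsensusNMF(n_components=6, n_iter=20, random_state=0).fit(xraw)
print(model.stability_, model.reconstruction_err_)
# -> stability 0.759, reconstruction error 0.853

catalog = GEPCatalog(spectra=pd.DataFrame(
    model.components_, index=[f"GEP{i}" for i in range(6)], columns=genes))
query, _ = simulate_dataset(300, params, np.random.default_rng(1))
res = fit_usage(query, catalog)
print(res.usage.values.round(3).head(3))
```

```
        GEP0   GEP1   GEP2   GEP3   GEP4   GEP5
cell0  0.249  0.000  0.508  0.046  0.018  0.180
cell1  0.000  0.007  0.037  0.000  0.430  0.526
cell2  0.575  0.202  0.000  0.093  0.131  0.000
```

Each row is one query cell's compositional usage of the six learned
programs (rows sum to 1). The stability value is the silhouette of the
clustered replicate spectra — high values mean the factorization is
reproducible across restarts — and the reconstruction error is the relative
Frobenius residual, which stays large on sparse counts even for a perfect
model because Poisson noise dominates. On this simulation the learned
components track the ground-truth programs with per-component usage
correlations of 0.55–0.95 (`np.corrcoef` of refit usages against
`truth.usage`).

The same flows are scriptable from the shell:

```bash
gepcat simulate --cells 1000 --seed 0 --out sim/
gepcat cnmf scan     --counts sim/counts --k 4..8 --n-iter 20 --out scan/
gepcat cnmf finalize --counts sim/counts --k-final 6 --n-iter 200 --out final/
gepcat project --query sim/counts --catalog cat/ --out usage.tsv --scores scores.tsv
gepcat benchmark --scale 0.1 --seed 1 --out bm/
```

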