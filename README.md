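# ecoassembly

Community-assembly inference and spatial multivariate statistics for soil
microbiome surveys.

`ecoassembly` reimplements, as a tested and reusable Python pipeline, the
statistical stack used in restoration-ecology microbiome studies that ask
*which ecological processes structure soil bacterial and fungal
communities*: deterministic environmental selection, dispersal, or drift.
It targets datasets of the usual survey shape — an ASV/feature count table,
a rooted phylogeny with branch lengths, and per-sample metadata (plot
design, coordinates in meters, soil chemistry) — and ships a synthetic
metacommunity simulator so every statistic can be validated against data
whose generating process is known.

## What it computes

**Two-step null-model classification of community assembly** (the core).
For each pair of communities *j, k*:

1. *Phylogenetic turnover.* The beta mean nearest taxon distance,

   βMNTD(j,k) = ½ [ Σ_{i∈j} f_ij · min_{i′∈k} d(i,i′) + Σ_{i∈k} f_ik · min_{i′∈j} d(i,i′) ],

   with f the within-sample relative abundances and d the patristic
   distance, is standardized against a null that shuffles tip labels
   across the observed taxa: βNTI = (βMNTD_obs − μ_null) / σ_null.
   βNTI < −2 indicates homogeneous selection, βNTI > +2 heterogeneous
   selection.
2. *Compositional turnover.* For pairs not resolved by selection, observed
   Bray–Curtis dissimilarity is compared to a stochastic assembly null
   that preserves each sample's richness and total abundance while drawing
   taxa by occurrence frequency and individuals by pool abundance:
   RC_Bray = 2·[(#(null < obs) + ½·#(null = obs))/n_null] − 1.
   RC > +0.95 indicates dispersal limitation (plus drift), RC < −0.95
   homogenizing dispersal, anything else is undominated.

**Around the core:** depth filtering, rarefaction (exact multivariate-
hypergeometric subsampling), cumulative-sum-scaling (CSS) normalization,
greedy collinearity pruning of chemistry (|r| > 0.65), Shannon diversity,
Bray–Curtis/Euclidean distances, principal coordinates analysis, sequential
(Type-I) PERMANOVA, Mantel tests and distance-decay fits, symmetric
Procrustes with a permutation test, DistLM forward selection, distance-based
Moran's eigenvector maps (dbMEM) with environment/space variance
partitioning (adjusted R²), and IndVal indicator analysis with
Benjamini–Hochberg correction.

## Worked example

Simulate a metacommunity assembled under homogeneous selection, run the
classifier, and summarize the inferred processes:

```python
from ecoassembly import (NullModelConfig, ScenarioConfig, align_inputs,
                         assemble_communities, classify_assembly,
                         summarize_processes)
from ecoassembly.preprocess import filter_low_depth, rarefy

ds = assemble_communities(ScenarioConfig(
    scenario="homogeneous_selection", rng_seed=1))
table, tree, frame = align_inputs(ds.table, ds.phylogeny, ds.frame)
table = filter_low_depth(table, min_sample_reads=1000)
rarefied = rarefy(table, int(table.row_sums().min()), seed=1)
pairs = classify_assembly(rarefied, tree.prune(rarefied.taxon_ids),
                          NullModelConfig(n_null=999, rng_seed=1))
print(summarize_processes(pairs).iloc[0][
    ["homogeneous_selection", "dispersal_limitation", "undominated"]])
```

Output:

```
homogeneous_selection    84.057971
dispersal_limitation     15.942029
undominated               0.000000
Name: 0, dtype: object
```

84% of the 276 sample pairs are attributed to homogeneous selection
(βNTI < −2): the classifier recovers the process the communities were
assembled under. The residual pairs leak into dispersal limitation because
the simulator also applies local drift (random extinctions and abundance
fluctuations), which for the weakest-selected pairs dominates the signal.

The same pipeline runs from the shell:

```bash
ecoassembly simulate --scenario homogeneous_selection --seed 1 --out data/
ecoassembly run-all --config config.yaml     # paths, seeds, toggles
```

Each run writes result TSVs plus a `manifest.json` recording versions,
seeds, the config hash, and per-stage sample/taxon counts; a rerun with the
same config is byte-identical.

## Layout

| module | contents |
| --- | --- |
| `ecoassembly.io` | table/tree/metadata readers and writers, cross-file alignment |
| `ecoassembly.preprocess` | depth filter, rarefaction, CSS, collinearity pruning |
| `ecoassembly.diversity` | Shannon, Bray–Curtis, Euclidean, PCoA |
| `ecoassembly.assembly` | βMNTD/βNTI, RC_Bray, process classification |
| `ecoassembly.multivariate` | PERMANOVA, Mantel/distance decay, Procrustes, DistLM |
| `ecoassembly.spatial` | dbMEM construction/selection, variance partitioning |
| `ecoassembly.indicator` | IndVal with permutation p-values and BH correction |
| `ecoassembly.simulate` | scenario-based metacommunity and functional-table simulator |
| `ecoassembly.pipeline` / `ecoassembly.cli` | end-to-end orchestration, manifest, CLI |

See `docs/methods.md` for the models, null-model conventions, simulator
design, and known limitations.
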