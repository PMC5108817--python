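# omiclayers

Multi-layer (multiplex) gene-network integration of multi-omic data.

Distinct omic assays describe the same genes through different relations:
functional similarity (GO-based), spatial proximity of loci in the
nucleus (Hi-C neighborhoods around a seed gene), and physical
protein–protein interaction.  `omiclayers` represents each relation as
one **layer** — an undirected gene graph whose edge weights are
probabilities of the relation existing, in [0, 1] — and assembles the
layers into a multiplex network, the quadruplet *M* = (*V_M*, *E_M*,
*V*, *L*): the gene universe *V*, the layer list *L*, the node-layer
presence set *V_M*, and the edge set *E_M* of intra-layer edges plus
inter-layer couplings between replicas of the same gene.  Scalar omic
tracks (methylation signal, expression, mutation sample counts) are
bound per gene to individual layers.

The package is aimed at systems-biology analyses that compare two
experimental conditions of such a network — e.g. a cancer cell line
before and after hormone stimulation — and ask which genes matter, how
the layers relate, and how pathogenic mutations accumulate.

## What it computes

* **Centrality diagnostics** per layer, on the aggregate layer (the sum
  of the layers' adjacency matrices) and for the whole multilayer model:
  degree *d_i* (count of incident edges), strength *s_i* (sum of
  incident edge weights), and HITS hub/authority scores.  On an
  undirected graph hub and authority coincide and equal the principal
  (Perron) eigenvector of the weighted adjacency; the whole-multilayer
  scores come from the supra-adjacency matrix, collapsed per gene as the
  Euclidean norm over its node-layer replicas.
* **Inter-layer assortativity**: the Pearson or Spearman correlation of
  a per-gene descriptor between every pair of layers, aligned on the
  gene union with absent genes scored 0, reported as an L×L matrix.
* **Driver/passenger mutation statistics**: SNPs with a pathogenicity
  score strictly above 0.7 (a cancer-weighted FATHMM-style score)
  classify as drivers, the rest as passengers; per-class counts and
  score moments (mean, median, sample variance) are tabulated overall
  and inside a pathway gene set.
* **Gene-set enrichment**: exact upper-tail hypergeometric probability
  (log-space tail sum) that the network's genes over-represent an
  annotated set — e.g. disease-associated genes — against a genome-wide
  universe.
* **Two-condition comparison**: per-gene degree/strength deltas, genes
  gained and lost per layer, assortativity and mutation-summary deltas,
  and qualitative signature flags (more genes, denser conformation
  neighborhood around the seed gene, more drivers after the stimulus).
* **Synthetic studies**: a generator that emulates the statistical
  structure of a seed-centric pre/post-stimulus experiment — layer
  growth by preferential attachment, planted inter-layer degree
  correlation, anti-correlated methylation/expression tracks, bimodal
  pathogenicity scores — with full planted truth, so every stage runs
  and is testable without downloads.

## Worked example

```python
import dataclasses
from omiclayers import (SimConfig, generate_study, write_study,
                        run_condition, compare_conditions)

cfg = dataclasses.replace(
    SimConfig(), n_genes_pre=30, n_genes_post=45,
    edge_density_pre=0.10, edge_density_post=0.15,
    n_snps_pre=400, n_snps_post=900, universe_size=300, rng_seed=7)
study = generate_study(cfg)
paths = write_study(study, "study")          # TSVs + run configs
pre = run_condition(paths["pre"])
post = run_condition(paths["post"])
cmp = compare_conditions(pre, post)

print("genes pre/post:", pre["gene_count"], post["gene_count"])
print("pre mutation counts:", pre["mutations"]["counts"])
print("top 5 multilayer strength:", pre["top_k"]["multilayer"]["strength"][:5])
print("enrichment p:", f"{pre['enrichment']['p_value']:.3g}")
print("signature flags:", cmp["signature_flags"])
```

prints

```
genes pre/post: 30 45
pre mutation counts: {'driver': 263, 'passenger': 137, 'unclassified': 0}
top 5 multilayer strength: ['ESR1', 'G0024', 'G0014', 'G0007', 'G0009']
enrichment p: 7e-06
signature flags: {'post_more_genes': True, 'post_more_drivers': True,
 'post_denser_conformation': True, 'post_seed_conformation_degree_higher': True}
```

The seed gene tops the multilayer strength ranking (the conformation
layer is grown around it), roughly 70% of the 400 pre-condition SNPs
classify as drivers at the 0.7 threshold, the planted disease-gene
enrichment is highly significant, and all four post-stimulus signature
flags hold: the post condition gains genes, densifies around the seed
gene, and accumulates drivers.

The same workflow is available from the shell via the `omiclayers`
command (`simulate`, `build`, `diagnose`, `correlate`, `mutstats`,
`enrich`, `run`, `compare`, `export`).

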