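{
 "condition": "pre",
 "coupling_weight": 1.0,
 "driver_threshold": 0.7,
 "gene_sets": {
  "disease": "disease_genes.txt",
  "metabolic": "metabolic_genes.txt"
 },
 "layers": {
  "conformation": "pre_conformation.edges.tsv",
  "interaction": "pre_interaction.edges.tsv",
  "similarity": "pre_similarity.edges.tsv"
 },
 "mutations": "pre_mutations.tsv",
 "p_threshold": 0.05,
 "seed_gene": "ESR1",
 "tracks": {
  "expression": {
   "layer": "interaction",
   "path": "pre_expression.tsv"
  },
  "methylation": {
   "layer": "conformation",
   "path": "pre_methylation.tsv"
  },
  "mutation_samples": {
   "layer": "similarity",
   "path": "pre_mutation_samples.tsv"
  }
 },
 "universe": "universe.txt"
}
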