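{
 "config": {
  "decoy_edge_fraction": 0.1,
  "disease_fraction_background": 0.05,
  "disease_fraction_graph": 0.3,
  "driver_fraction": 0.7,
  "driver_score_shape": [
   48.0,
   2.0
  ],
  "driver_threshold": 0.7,
  "edge_density_post": 0.15,
  "edge_density_pre": 0.1,
  "interlayer_mixing": 0.5,
  "metabolic_fraction": 0.1,
  "methylation_expression_corr": -0.5,
  "n_genes_post": 45,
  "n_genes_pre": 30,
  "n_snps_post": 900,
  "n_snps_pre": 400,
  "passenger_score_shape": [
   2.0,
   8.0
  ],
  "rng_seed": 7,
  "seed_attach_prob": 0.6,
  "seed_gene": "ESR1",
  "track_coverage": 0.9,
  "universe_size": 300
 },
 "driver_fraction": 0.7,
 "driver_score_mean": 0.96,
 "genes_gained": 15,
 "interlayer_mixing": 0.5,
 "methylation_expression_corr": -0.5,
 "n_genes_post": 45,
 "n_genes_pre": 30,
 "passenger_score_mean": 0.2,
 "post_driver_count": 619,
 "post_planted_driver_count": 619,
 "post_seed_conformation_degree": 30,
 "pre_driver_count": 263,
 "pre_planted_driver_count": 263,
 "pre_seed_conformation_degree": 18,
 "seed_gene": "ESR1"
}
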