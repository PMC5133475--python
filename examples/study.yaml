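# Synthetic family replication study: 20 families, block-LD genotypes,
# four annual exams, one injected interaction on the expression trait.
seed: 1
out_dir: runs/demo
simulate:
  n_families: 20
  family_size_mean: 48
  n_snps: 100
  block_size: 10
  within_block_r: 0.8
  maf_range: [0.05, 0.5]
  n_exams: 4
  trait_heritability: 0.3
  interaction_effect: 0.5
  residual_sd: 8.0
analysis:
  method: ML
  replicates: 100000
  alpha: 0.05
  phenotypes: [DBP, MAP, PP, SBP, HTN]
  interaction_pair: [snp5, snp75]
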