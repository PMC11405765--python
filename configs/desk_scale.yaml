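# Default desk-scale run: 150 F2s, 5 chromosomes x 5 Mb, one PVE-0.15 QTL
# on chr3 over a polygenic background, mapped with 10 permutations.
seed: 11
simulate:
  chromosomes:
    - [chr1, 5000000]
    - [chr2, 5000000]
    - [chr3, 5000000]
    - [chr4, 5000000]
    - [chr5, 5000000]
  bin_size: 5000
  snp_density: 0.004        # one informative SNP per 250 bp
  crossover_mean: 0.8       # per chromosome per meiosis
  depth_mean: 1.0           # reads per SNP site
  seq_error: 0.002
  n_f2: 150
  qtl:
    - {chrom: chr3, bin: 500, pve: 0.15}
  polygenic_var: 0.3
  residual_var: 1.0
  batch_effects: {scope1: 0.0, scope2: 3.5}
genotype:
  emission_var: 0.8
  trans_prob: 1.0e-08
  qc_min_informative: 0.5
phenotype:
  normalization: invnorm
map:
  n_perm: 10
  alpha: 0.05
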