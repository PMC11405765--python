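# crossqtl

Desk-scale QTL mapping for an interspecies F2 fish cross, end to end and
with known ground truth.

Developmental traits such as the segmentation-clock period (the rate at
which somites form, read out from an oscillatory *her7* reporter) and
presomitic-mesoderm size vary heritably between fish strains.  A standard
way to map the loci behind that variation is an F2 intercross: two inbred
strains are crossed, the heterozygous F1s are incrossed, and each F2
genome is a unique mosaic of the two parental haplotypes delimited by
meiotic crossovers.  Shallow (~1x) whole-genome sequencing then suffices
to reconstruct each mosaic, and a mixed-model association scan links
genotype blocks to phenotypes.

`crossqtl` implements that entire statistical path as a tested Python
library, exercised on synthetic data whose truth is known:

* **simulate** — F2 genomes from Poisson crossovers (mean 0.8 per
  chromosome per meiosis), ~1x allele read counts at homozygous-divergent
  SNPs, QTL-structured phenotypes with polygenic background and batch
  effects, and oscillatory reporter traces;
* **genotype** — per-5-kb-bin Kaga-allele read fractions (empty bins at
  0.5) decoded by a 3-state Gaussian HMM (means 0/0.5/1, variance 0.8,
  off-diagonal transitions 1e-8) into long recombination blocks, with the
  previous/next-bin filling rule and coverage QC;
* **period** — sinc detrend (cut-off 100 min), sliding-envelope
  normalisation (window 150 min), Morlet wavelet ridge on 200 periods in
  [40, 100] min, and mean/intercept period summaries over a 300-min
  window;
* **traits** — within-batch rank-based inverse normal transform
  z = Φ⁻¹(rank/(N+0.5)), batch mean-equating, oblate-spheroid egg volume
  V = (4/3)πb²c;
* **association** — GCTA-style GRM, leave-one-chromosome-out REML mixed
  model, per-marker Wald chi-square, genome-wide significance from the
  minimum p over 10 phenotype permutations plus a Bonferroni 0.05/M line.

The model per tested pseudo-SNP x is

    y = Wα + xβ + g + ε,   g ~ N(0, σ²_g G_loco),   ε ~ N(0, σ²_e I)

with G_loco the relatedness matrix from all chromosomes except the tested
one.  See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from crossqtl import (CrossSimConfig, simulate_f2_cohort, bin_allele_counts,
                      decode_genotypes, fill_missing, build_pseudosnps,
                      simulate_phenotypes, inverse_normalize, effect_for_pve,
                      loco_grm, association_scan, permutation_threshold,
                      call_significant)

cfg = CrossSimConfig(n_f2=300, seed=7,
                     qtl_spec=[("chr3", 500, effect_for_pve(0.2))])
truth, counts = simulate_f2_cohort(cfg)
freqs = bin_allele_counts(counts, counts.panel, cfg.layout)
calls = fill_missing(decode_genotypes(freqs))
pseudo = build_pseudosnps(calls)

pheno = simulate_phenotypes(truth, cfg)
y = inverse_normalize(pheno["value"], pheno["batch"])

grms = {c: loco_grm(pseudo, c) for c in cfg.layout.names}
scan = association_scan(y, pseudo, grms)
thr, _ = permutation_threshold(y, pseudo, grms, n_perm=10, seeds=range(10))
print(call_significant(scan, thr)[["chrom", "peak_bin", "peak_p"]])
```

prints (the QTL was planted at chr3 bin 500, i.e. 2.500–2.505 Mb):

```
  chrom              peak_bin        peak_p
0  chr3  chr3:2610000-2615000  6.855817e-14
1  chr3  chr3:3840000-3845000  3.574358e-04
2  chr3  chr3:3990000-3995000  8.628321e-04
3  chr3  chr3:4015000-4020000  8.335471e-04
```

The strongest locus peaks ~110 kb from the planted bin at p ≈ 7e-14 —
recombination-block linkage at n = 300 sets that localisation scale — and
the trailing loci are blocks correlated with it on the same chromosome,
just clearing the 10-permutation threshold.

The same workflow is available as numbered drivers under `analysis/`
(simulation, genotyping, period extraction, batch normalisation, one full
mapping run, replicate-level calibration), each printing what it found and
writing small tables under `results/`, and as a CLI
(`crossqtl run --config cfg.yaml --out run/ --seed 1`, plus per-stage
subcommands `simulate`, `genotype`, `period`, `traits`, `qtl`).

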