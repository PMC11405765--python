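#!/usr/bin/env python
"""Demonstrate the two batch normalisations on a microscope-shifted trait.

Simulates a cohort whose clock-period phenotype carries an additive
between-microscope shift (the study design images on two scopes whose
incubation temperature differs slightly), then applies (a) within-batch
rank-based inverse normalisation and (b) mean-equating to a reference
batch, and reports the batch offset before and after each correction.
"""

import os

import pandas as pd

from crossqtl import (
    CrossSimConfig,
    equate_batch_means,
    inverse_normalize,
    simulate_f2_cohort,
    simulate_phenotypes,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11

os.makedirs(OUT, exist_ok=True)
# 3.5-min shift between scopes, on a ~58-min baseline trait
cfg = CrossSimConfig(
    n_f2=600, seed=SEED, depth_mean=0.0, residual_var=9.0,
    batch_effects={"scope1": 58.0, "scope2": 61.5},
)
truth, _ = simulate_f2_cohort(cfg)
pheno = simulate_phenotypes(truth, cfg)

pheno["invnorm"] = inverse_normalize(pheno["value"], pheno["batch"])
pheno["equated"] = equate_batch_means(pheno["value"], pheno["batch"], "scope1")

offset = lambda col: (
    pheno.loc[pheno.batch == "scope2", col].mean()
    - pheno.loc[pheno.batch == "scope1", col].mean()
)
table = pd.DataFrame(
    {
        "normalisation": ["none", "inverse_normal", "mean_equating"],
        "batch_offset": [offset("value"), offset("invnorm"), offset("equated")],
    }
)
table.to_csv(os.path.join(OUT, "04_batch_normalisation.tsv"), sep="\t", index=False)
print(table.to_string(index=False))
print("\nBoth corrections drive the between-scope offset to ~0; the inverse "
      "normalisation additionally forces each batch to a standard-normal scale.")
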