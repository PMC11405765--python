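#!/usr/bin/env python
"""Simulate the desk-scale F2 cross and summarise its ground truth.

Generates the default cohort (150 F2s, 5 chromosomes x 5 Mb, ~20
informative SNPs per 5-kb bin, crossovers Poisson with mean 0.8 per
chromosome per meiosis, ~1x coverage) and writes summary tables of what
the downstream stages will have to recover: true genotype-state
fractions, crossover counts, and read-depth distribution.
"""

import os

import numpy as np
import pandas as pd

from crossqtl import CrossSimConfig, simulate_f2_cohort

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11

os.makedirs(OUT, exist_ok=True)
cfg = CrossSimConfig(n_f2=150, seed=SEED)
truth, counts = simulate_f2_cohort(cfg)

state_fracs = {s: float((truth.states == s).mean()) for s in (0, 1, 2)}
co_per_chrom = np.array(
    [
        [g1.crossovers[c].size + g2.crossovers[c].size for c in cfg.layout.names]
        for g1, g2 in truth.gametes
    ]
)
depth = np.concatenate(
    [(counts.cab[c] + counts.kaga[c]).ravel() for c in cfg.layout.names]
)

summary = pd.DataFrame(
    {
        "quantity": [
            "n_f2",
            "n_panel_snps",
            "n_bins",
            "true_frac_hom_cab",
            "true_frac_het",
            "true_frac_hom_kaga",
            "mean_crossovers_per_chrom_pair",
            "mean_read_depth_per_snp",
        ],
        "value": [
            cfg.n_f2,
            counts.panel.n_sites,
            cfg.layout.total_bins,
            state_fracs[0],
            state_fracs[1],
            state_fracs[2],
            float(co_per_chrom.mean()),
            float(depth.mean()),
        ],
    }
)
summary.to_csv(os.path.join(OUT, "01_simulation_summary.tsv"), sep="\t", index=False)
print(summary.to_string(index=False))
print(
    f"\nTrue state fractions sit at the Mendelian 0.25/0.5/0.25 expectation; "
    f"both-gamete crossovers average {co_per_chrom.mean():.2f} per chromosome "
    f"(2 x 0.8 expected), and coverage is ~{depth.mean():.2f}x per site."
)
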