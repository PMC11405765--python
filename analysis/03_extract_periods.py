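#!/usr/bin/env python
"""Recover oscillation periods from synthetic reporter traces.

Simulates noisy, drifting, amplitude-decaying traces for a grid of true
periods spanning the biological range and runs the full wavelet pipeline
(sinc detrend, envelope normalisation, Morlet ridge, 300-min summaries),
tabulating the recovery error of the mean- and intercept-period summaries.
"""

import os

import numpy as np
import pandas as pd

from crossqtl import extract_period, simulate_oscillation

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11
TRUE_PERIODS = [45.0, 50.0, 55.0, 60.0, 65.0]
N_TRACES = 25

os.makedirs(OUT, exist_ok=True)
rng = np.random.default_rng(SEED)
rows = []
for true_p in TRUE_PERIODS:
    for i in range(N_TRACES):
        trace = simulate_oscillation(
            true_p, amplitude=1.0, trend_slope=0.002, envelope_rate=-0.002,
            noise_sd=0.2, duration_min=700.0, rng=rng,
        )
        est = extract_period(trace)
        rows.append(
            {
                "true_period": true_p,
                "replicate": i,
                "mean_period": est.mean_period,
                "intercept_period": est.intercept_period,
            }
        )
df = pd.DataFrame(rows)
df.to_csv(os.path.join(OUT, "03_period_recovery.tsv"), sep="\t", index=False)

summary = (
    df.assign(err=lambda d: d.mean_period - d.true_period)
    .groupby("true_period")["err"]
    .agg(["mean", "std", lambda e: np.abs(e).max()])
    .rename(columns={"<lambda_0>": "max_abs"})
)
print("mean-period recovery error (min) by true period:")
print(summary.round(3).to_string())
print("\nall traces recovered within +/-1.5 min:",
      bool((df.mean_period - df.true_period).abs().le(1.5).all()))
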