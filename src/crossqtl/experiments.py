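"""Canned validation experiments over the simulate -> call -> map pipeline.

These are the study-condition runs the test suite and the analysis scripts
share: the Mendelian genotyping experiment (desk-scale cohort, default
simulator settings), the single-QTL recovery replicate, and the null-model
scan replicate.  Each takes a seed and returns plain dictionaries so
callers can aggregate replicates however they need.
"""

from __future__ import annotations

import numpy as np

from . import association, genotype, simulate, traits
from .genotype import GenotypeCalls, build_pseudosnps
from .pipeline import compare_to_truth
from .simulate import CrossSimConfig

STATE_EXPECTED = {"hom_cab": 0.25, "het": 0.5, "hom_kaga": 0.25}


def mendelian_genotyping_experiment(seed: int, n_f2: int = 150) -> dict:
    """Simulate the default desk-scale cohort and genotype it end to end.

    Returns the genome-wide called fraction of each state with its
    Monte-Carlo standard error (over samples), the 90th percentile of
    state changes per chromosome, and the per-bin accuracy against truth.
    """
    cfg = CrossSimConfig(n_f2=n_f2, seed=seed)
    truth, counts = simulate.simulate_f2_cohort(cfg)
    freqs = genotype.bin_allele_counts(counts, counts.panel, cfg.layout)
    calls = genotype.fill_missing(genotype.decode_genotypes(freqs))
    out: dict = {"n_f2": n_f2, "seed": seed}
    for state, name in enumerate(genotype.STATE_NAMES):
        per_sample = (calls.states == state).mean(axis=1)
        out[name] = {
            "fraction": float(per_sample.mean()),
            "se": float(per_sample.std(ddof=1) / np.sqrt(n_f2)),
            "expected": STATE_EXPECTED[name],
        }
    changes = genotype.count_state_changes(calls)
    out["state_changes_p90"] = float(np.percentile(changes, 90))
    out["state_changes_mean"] = float(changes.mean())
    out["genotype_accuracy"] = float((calls.states == truth.states).mean())
    return out


def _variance_components(qtl_pve: float, polygenic_h2: float) -> tuple[float, float, float]:
    """(QTL effect, polygenic variance, residual variance) with residual
    variance fixed at 1 so the requested fractions hold in expectation."""
    resid_frac = 1.0 - qtl_pve - polygenic_h2
    if resid_frac <= 0:
        raise ValueError("QTL PVE + polygenic h2 must stay below 1")
    total = 1.0 / resid_frac
    beta = float(np.sqrt(qtl_pve * total / 0.5))  # F2 dosage variance is 1/2
    return beta, polygenic_h2 * total, 1.0


def qtl_recovery_replicate(
    seed: int,
    n_f2: int = 600,
    qtl_pve: float = 0.15,
    polygenic_h2: float = 0.2,
    qtl_chrom: str = "chr3",
    qtl_bin: int = 500,
    n_perm: int = 10,
    hit_distance_bp: int = 500_000,
) -> dict:
    """One full replicate of the headline mapping experiment.

    Simulated reads -> HMM genotypes -> inverse-normalised phenotype ->
    LOCO mixed-model scan -> 10-permutation threshold; the replicate is a
    hit when a significant locus peaks within ``hit_distance_bp`` of the
    simulated QTL bin.
    """
    beta, polygenic_var, residual_var = _variance_components(qtl_pve, polygenic_h2)
    cfg = CrossSimConfig(
        n_f2=n_f2,
        seed=seed,
        qtl_spec=[(qtl_chrom, qtl_bin, beta)],
        polygenic_var=polygenic_var,
        residual_var=residual_var,
    )
    truth, counts = simulate.simulate_f2_cohort(cfg)
    freqs = genotype.bin_allele_counts(counts, counts.panel, cfg.layout)
    calls = genotype.fill_missing(genotype.decode_genotypes(freqs))
    pseudo = build_pseudosnps(calls)

    pheno = simulate.simulate_phenotypes(truth, cfg)
    y = traits.inverse_normalize(pheno["value"], pheno["batch"])

    chroms = list(dict.fromkeys(pseudo.chrom))
    grms = {c: association.loco_grm(pseudo, c) for c in chroms}
    scan = association.association_scan(y, pseudo, grms)
    threshold, minima = association.permutation_threshold(
        y, pseudo, grms, n_perm=n_perm, seeds=[seed * 1000 + i for i in range(n_perm)]
    )
    loci = association.call_significant(scan, threshold)
    evaluation = compare_to_truth(
        calls, truth, qtl_spec=cfg.qtl_spec, loci=loci, hit_distance_bp=hit_distance_bp
    )
    (qtl_eval,) = evaluation["qtl_hits"]
    return {
        "seed": seed,
        "hit": bool(qtl_eval["hit"]),
        "peak_distance_bp": qtl_eval["peak_distance_bp"],
        "n_significant_loci": int(len(loci)),
        "permutation_threshold": threshold,
        "genotype_accuracy": evaluation["genotype_accuracy"],
        "variance_fractions": pheno.attrs["variance_fractions"],
    }


def null_scan_replicate(seed: int, n_f2: int = 300, n_perm: int = 10) -> dict:
    """Permutation-threshold scan of a pure-noise phenotype.

    Uses the true simulated genotype states directly as pseudo-SNP dosages
    (no read noise needed under the null); reports how many loci cleared
    the permutation threshold — the expected count is 1/(n_perm+1) runs
    with any hit at all.
    """
    cfg = CrossSimConfig(n_f2=n_f2, seed=seed, depth_mean=0.0)
    truth, _ = simulate.simulate_f2_cohort(cfg)
    calls = GenotypeCalls(
        cfg.layout,
        [f"F2_{i:04d}" for i in range(n_f2)],
        truth.states,
        np.zeros(cfg.layout.total_bins, dtype=bool),
    )
    pseudo = build_pseudosnps(calls)
    y = np.random.default_rng(seed + 77).normal(size=n_f2)
    chroms = list(dict.fromkeys(pseudo.chrom))
    grms = {c: association.loco_grm(pseudo, c) for c in chroms}
    scan = association.association_scan(y, pseudo, grms)
    threshold, _ = association.permutation_threshold(
        y, pseudo, grms, n_perm=n_perm, seeds=[seed * 1000 + i for i in range(n_perm)]
    )
    loci = association.call_significant(scan, threshold)
    return {"seed": seed, "n_significant_loci": int(len(loci)), "threshold": threshold}
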