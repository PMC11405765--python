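"""End-to-end orchestration: simulate -> genotype -> phenotype -> map.

One YAML config drives a reproducible run.  A single global seed spawns
independent per-stage seeds via ``numpy.random.SeedSequence`` so partial
re-runs stay deterministic.  Every stage writes its tables under the
output directory with stable names, and the run report records row
counts, QC exclusions, thresholds and significant loci in both a
human-readable text file and machine-readable JSON.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association, genotype, io, period, simulate, traits
from .genome import GenomeLayout


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "genotype", "phenotype", "map"]
    )
    # simulate
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i + 1}", 5_000_000) for i in range(5)]
    )
    bin_size: int = 5000
    snp_density: float = 1.0 / 250.0
    crossover_mean: float = 0.8
    depth_mean: float = 1.0
    seq_error: float = 0.002
    n_f2: int = 150
    qtl: list[dict[str, Any]] = field(default_factory=list)  # chrom, bin, or pve/effect
    polygenic_var: float = 0.0
    residual_var: float = 1.0
    batch_effects: dict[str, float] = field(default_factory=lambda: {"scope1": 0.0, "scope2": 0.0})
    write_allele_counts: bool = False
    # phenotype
    trace_phenotyping: bool = False
    base_period_min: float = 55.0
    trace_duration_min: float = 700.0
    trace_noise_sd: float = 0.1
    normalization: str = "invnorm"  # invnorm | equate | none
    reference_batch: str | None = None
    # genotype
    emission_var: float = 0.8
    trans_prob: float = 1e-8
    qc_min_informative: float = 0.5
    # map
    n_perm: int = 10
    alpha: float = 0.05
    use_batch_covariate: bool = False

    def layout(self) -> GenomeLayout:
        return GenomeLayout(tuple((c, int(l)) for c, l in self.chromosomes), self.bin_size)

    def validate(self) -> None:
        self.layout()
        if self.normalization not in ("invnorm", "equate", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        unknown = set(self.stages) - {"simulate", "genotype", "phenotype", "map"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key in ("simulate", "genotype", "phenotype", "map"):
                flat.update(val)
            else:
                flat[key] = val
        cfg = cls(**flat)
        cfg.validate()
        return cfg


def _resolve_qtl_spec(cfg: RunConfig) -> list[tuple[str, int, float]]:
    """Turn config QTL entries into (chrom, bin, effect); a 'pve' entry is
    converted to an additive effect against the configured background
    variance."""
    spec = []
    background = cfg.polygenic_var + cfg.residual_var
    for q in cfg.qtl:
        if "effect" in q:
            beta = float(q["effect"])
        else:
            beta = simulate.effect_for_pve(float(q["pve"]), background_var=background)
        spec.append((q["chrom"], int(q["bin"]), beta))
    return spec


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the report."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "config.resolved.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(("simulate", "genotype", "phenotype", "map"), seeds)
    }
    report: dict[str, Any] = {"seed": config.seed, "stage_seeds": stage_seed, "stages": {}}
    layout = config.layout()
    t_start = time.time()

    truth = counts = panel = None
    calls = pseudo = None
    trait_table = None

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            sim_cfg = simulate.CrossSimConfig(
                layout=layout,
                snp_density=config.snp_density,
                crossover_mean=config.crossover_mean,
                depth_mean=config.depth_mean,
                seq_error=config.seq_error,
                n_f2=config.n_f2,
                qtl_spec=_resolve_qtl_spec(config),
                polygenic_var=config.polygenic_var,
                residual_var=config.residual_var,
                batch_effects=config.batch_effects,
                seed=stage_seed["simulate"],
            )
            truth, counts = simulate.simulate_f2_cohort(sim_cfg)
            panel = counts.panel
            io.write_layout(layout, os.path.join(out, "layout.tsv"))
            io.write_panel_tsv(panel, os.path.join(out, "panel.tsv"))
            io.write_panel_vcf(panel, os.path.join(out, "panel.vcf"))
            if config.write_allele_counts:
                io.write_allele_counts(counts, os.path.join(out, "allele_counts.tsv"))
            report["stages"]["simulate"] = {
                "n_f2": truth.n_samples,
                "n_panel_snps": panel.n_sites,
                "n_bins": layout.total_bins,
                "qtl_spec": [list(q) for q in sim_cfg.qtl_spec],
                "seconds": round(time.time() - t0, 2),
            }

        if "genotype" in config.stages:
            t0 = time.time()
            if counts is None:
                raise RuntimeError("genotype stage needs the simulate stage in this run")
            freqs = genotype.bin_allele_counts(counts, panel, layout)
            kept, excluded, frac = genotype.qc_samples(freqs, config.qc_min_informative)
            spec = genotype.HMMSpec(
                emission_var=config.emission_var, trans_prob=config.trans_prob
            )
            calls = genotype.fill_missing(genotype.decode_genotypes(freqs, spec))
            pseudo = genotype.build_pseudosnps(calls)
            changes = genotype.count_state_changes(calls)
            io.write_pseudosnps(pseudo, os.path.join(out, "pseudosnps.tsv"))
            frac_counts = [
                float((calls.states == s).mean()) for s in (0, 1, 2)
            ]
            report["stages"]["genotype"] = {
                "n_samples": len(calls.sample_ids),
                "n_calls": int(calls.states.size),
                "qc_kept": len(kept),
                "qc_excluded": excluded,
                "state_fractions": dict(zip(genotype.STATE_NAMES, frac_counts)),
                "mean_state_changes_per_chrom": float(changes.mean()),
                "seconds": round(time.time() - t0, 2),
            }

        if "phenotype" in config.stages:
            t0 = time.time()
            if truth is None:
                raise RuntimeError("phenotype stage needs the simulate stage in this run")
            rng = np.random.default_rng(stage_seed["phenotype"])
            sim_cfg = simulate.CrossSimConfig(
                layout=layout,
                n_f2=config.n_f2,
                qtl_spec=_resolve_qtl_spec(config),
                polygenic_var=config.polygenic_var,
                residual_var=config.residual_var,
                batch_effects=config.batch_effects,
                seed=stage_seed["phenotype"],
            )
            pheno = simulate.simulate_phenotypes(truth, sim_cfg, rng)
            if config.trace_phenotyping:
                # phenotype value shifts the oscillation period around the base
                settings = period.WaveletSettings()
                measured = []
                for val in pheno["value"]:
                    tr = simulate.simulate_oscillation(
                        period_min=config.base_period_min + val,
                        amplitude=1.0,
                        trend_slope=0.002,
                        envelope_rate=-0.001,
                        noise_sd=config.trace_noise_sd,
                        duration_min=config.trace_duration_min,
                        rng=rng,
                    )
                    est = period.extract_period(tr, settings)
                    measured.append((est.mean_period, est.intercept_period))
                pheno["period_mean"] = [m[0] for m in measured]
                pheno["period_intercept"] = [m[1] for m in measured]
                analysis_col = "period_intercept"
            else:
                pheno["period_mean"] = pheno["value"]
                pheno["period_intercept"] = pheno["value"]
                analysis_col = "value"
            if config.normalization == "invnorm":
                pheno["analysis_value"] = traits.inverse_normalize(
                    pheno[analysis_col], pheno["batch"]
                )
            elif config.normalization == "equate":
                ref = config.reference_batch or sorted(config.batch_effects)[0]
                pheno["analysis_value"] = traits.equate_batch_means(
                    pheno[analysis_col], pheno["batch"], ref
                )
            else:
                pheno["analysis_value"] = pheno[analysis_col]
            io.write_traits(pheno, os.path.join(out, "traits.tsv"))
            trait_table = pheno
            report["stages"]["phenotype"] = {
                "n_samples": len(pheno),
                "normalization": config.normalization,
                "variance_fractions": pheno.attrs.get("variance_fractions", {}),
                "trace_phenotyping": config.trace_phenotyping,
                "seconds": round(time.time() - t0, 2),
            }

        if "map" in config.stages:
            t0 = time.time()
            if pseudo is None or trait_table is None:
                raise RuntimeError("map stage needs genotype and phenotype stages in this run")
            y = trait_table["analysis_value"].to_numpy(dtype=float)
            covar = None
            if config.use_batch_covariate:
                covar = pd.get_dummies(trait_table["batch"], drop_first=True).to_numpy(float)
            chroms = list(dict.fromkeys(pseudo.chrom))
            grms = {c: association.loco_grm(pseudo, c) for c in chroms}
            scan = association.association_scan(y, pseudo, grms, covar)
            perm_seeds = [int(stage_seed["map"] + i) for i in range(config.n_perm)]
            perm_thr, perm_minima = association.permutation_threshold(
                y, pseudo, grms, covar, n_perm=config.n_perm, seeds=perm_seeds
            )
            bonf_thr = association.bonferroni_threshold(pseudo.shape[1], config.alpha)
            loci = association.call_significant(scan, perm_thr, bonf_thr)
            scan["sig_perm"] = scan["p"] < perm_thr
            scan["sig_bonf"] = scan["p"] < bonf_thr
            io.write_association(scan, os.path.join(out, "association.tsv"))
            io.write_association(loci, os.path.join(out, "loci.tsv"))
            with open(os.path.join(out, "thresholds.json"), "w") as fh:
                json.dump(
                    {
                        "permutation": perm_thr,
                        "per_permutation_minima": perm_minima,
                        "bonferroni": bonf_thr,
                    },
                    fh,
                    indent=2,
                )
            report["stages"]["map"] = {
                "n_pseudosnps": int(pseudo.shape[1]),
                "permutation_threshold": perm_thr,
                "bonferroni_threshold": bonf_thr,
                "n_significant_loci": int(len(loci)),
                "loci": loci.to_dict("records"),
                "seconds": round(time.time() - t0, 2),
            }
    except Exception as exc:  # partial outputs stay on disk for inspection
        report["failed_stage"] = _current_stage(report, config.stages)
        report["error"] = str(exc)
        _write_report(report, out, time.time() - t_start)
        raise

    _write_report(report, out, time.time() - t_start)
    return report


def _current_stage(report: dict, stages: list[str]) -> str:
    done = set(report["stages"])
    for s in stages:
        if s not in done:
            return s
    return "unknown"


def _write_report(report: dict, out: str, elapsed: float) -> None:
    report["total_seconds"] = round(elapsed, 2)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    lines = [f"pipeline run (seed {report['seed']})", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            if k == "loci":
                lines.append(f"  significant loci: {len(v)}")
                for loc in v:
                    lines.append(
                        f"    {loc['chrom']}:{loc['start']}-{loc['end']} "
                        f"peak {loc['peak_bin']} p={loc['peak_p']:.3g}"
                    )
            else:
                lines.append(f"  {k}: {v}")
        lines.append("")
    if "error" in report:
        lines.append(f"FAILED at stage {report['failed_stage']}: {report['error']}")
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def compare_to_truth(
    calls,
    truth,
    qtl_spec: list[tuple[str, int, float]] | None = None,
    loci=None,
    hit_distance_bp: int = 500_000,
) -> dict:
    """Score a run against simulation ground truth.

    Reports per-bin genotype accuracy, median crossover-breakpoint
    localisation error (distance from each true crossover to the nearest
    called state-change boundary), and — when a QTL spec and called loci
    are given — whether each true QTL has a called peak within
    ``hit_distance_bp``.
    """
    if calls.states.shape != truth.states.shape:
        raise ValueError("calls and truth have mismatched shapes")
    layout = truth.layout
    accuracy = float((calls.states == truth.states).mean())

    offsets = layout.bin_offsets
    errors = []
    for i, (g1, g2) in enumerate(truth.gametes):
        for chrom in layout.names:
            o = offsets[chrom]
            nb = layout.n_bins(chrom)
            st = calls.states[i, o : o + nb]
            bounds = (np.flatnonzero(np.diff(st) != 0) + 1) * layout.bin_size
            for gam in (g1, g2):
                for pos in gam.crossovers[chrom]:
                    if bounds.size:
                        errors.append(float(np.min(np.abs(bounds - pos))))
    evaluation = {
        "genotype_accuracy": accuracy,
        "n_true_crossovers": len(errors),
        "median_breakpoint_error_bp": float(np.median(errors)) if errors else 0.0,
    }
    if qtl_spec is not None and loci is not None:
        hits = []
        for chrom, bin_k, _ in qtl_spec:
            true_pos = bin_k * layout.bin_size + layout.bin_size // 2
            on = loci[loci["chrom"] == chrom] if len(loci) else loci
            d = (
                float(np.min(np.abs(on["peak_start"].to_numpy() + layout.bin_size // 2 - true_pos)))
                if len(on)
                else np.inf
            )
            hits.append({"chrom": chrom, "bin": bin_k, "peak_distance_bp": d, "hit": d <= hit_distance_bp})
        evaluation["qtl_hits"] = hits
    return evaluation
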