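"""Synthetic F2 intercross generator with known ground truth.

Two fully inbred parental strains (call them Cab-type and Kaga-type) are
crossed; the F1 is heterozygous at every panel site; incrossing F1s yields
F2 individuals whose genomes are mosaics of the two parental haplotypes,
delimited by meiotic crossovers.  Crossovers are Poisson along each
chromosome with no interference (the field's baseline model when only a
mean rate — here under one per chromosome per meiosis — is known).

The generator produces, per F2 sample:

* true per-bin genotype states (0 hom-Cab, 1 het, 2 hom-Kaga) and the
  crossover positions of both gametes,
* per-SNP allele read counts at roughly 1x depth (Poisson reads, each read
  drawn from one of the two haplotypes, flipped by a small error rate),
* quantitative phenotypes with configurable QTL effects, a polygenic
  background matching the additive-GRM assumption, batch shifts and noise,
* raw oscillatory reporter traces at a fixed sampling interval for the
  period-extraction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, SNPPanel, random_divergent_alleles

#: state codes
HOM_CAB, HET, HOM_KAGA = 0, 1, 2

DEFAULT_LAYOUT = GenomeLayout(
    chromosomes=tuple((f"chr{i + 1}", 5_000_000) for i in range(5)),
    bin_size=5000,
)


@dataclass
class CrossSimConfig:
    """Parameters of the synthetic F2 cohort.

    Defaults are a desk-scale genome (5 chromosomes x 5 Mb, 5-kb bins, one
    SNP per 250 bp, so ~20 informative sites per bin) sequenced at ~1x,
    with crossovers averaging 0.8 per chromosome per meiosis.
    """

    layout: GenomeLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    snp_density: float = 1.0 / 250.0
    crossover_mean: float = 0.8
    depth_mean: float = 1.0
    seq_error: float = 0.002
    n_f2: int = 150
    qtl_spec: list[tuple[str, int, float]] = field(default_factory=list)
    polygenic_var: float = 0.0
    residual_var: float = 1.0
    batch_effects: dict[str, float] = field(default_factory=lambda: {"scope1": 0.0, "scope2": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crossover_mean < 0:
            raise ValueError("crossover_mean must be >= 0")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class Gamete:
    """One meiotic product: per chromosome, a starting haplotype origin
    (0 = Cab, 1 = Kaga) and sorted crossover positions at which the origin
    alternates."""

    start_origin: dict[str, int]
    crossovers: dict[str, np.ndarray]

    def origin_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Haplotype origin (0/1) at base-pair positions on one chromosome."""
        br = self.crossovers[chrom]
        flips = np.searchsorted(br, np.asarray(pos), side="right")
        return (self.start_origin[chrom] + flips) % 2


@dataclass
class TrueGenotypes:
    """Ground-truth per-bin states and the crossovers that produced them."""

    layout: GenomeLayout
    states: np.ndarray  # (n_samples, total_bins) int8, genome bin order
    gametes: list[tuple[Gamete, Gamete]]

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]


@dataclass
class AlleleCounts:
    """Per-sample, per-panel-SNP reads supporting each parental allele."""

    panel: SNPPanel
    cab: dict[str, np.ndarray]  # chrom -> (n_samples, n_sites) uint16
    kaga: dict[str, np.ndarray]
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class OscillationTrace:
    """Evenly sampled reporter-intensity trace (arbitrary units)."""

    interval_min: float
    values: np.ndarray
    true_period_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.interval_min <= 0:
            raise ValueError("sampling interval must be positive")
        if self.values.size < 2:
            raise ValueError("trace needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.interval_min


def simulate_panel(config: CrossSimConfig, rng: np.random.Generator | None = None) -> SNPPanel:
    """Place homozygous-divergent SNPs uniformly at the configured density."""
    if config.snp_density <= 0:
        raise ValueError("snp_density must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    positions: dict[str, np.ndarray] = {}
    cab: dict[str, np.ndarray] = {}
    kaga: dict[str, np.ndarray] = {}
    for chrom, length in config.layout.chromosomes:
        n = rng.poisson(config.snp_density * length)
        pos = np.unique(rng.integers(0, length, size=n))
        positions[chrom] = pos.astype(np.int64)
        cab[chrom], kaga[chrom] = random_divergent_alleles(pos.size, rng)
    return SNPPanel(config.layout, positions, cab, kaga)


def simulate_meiosis(
    layout: GenomeLayout, crossover_mean: float, rng: np.random.Generator
) -> Gamete:
    """Draw one gamete of an F1: Poisson(crossover_mean) crossovers per
    chromosome at uniform positions, no interference, fair starting strand."""
    if crossover_mean < 0:
        raise ValueError("crossover_mean must be >= 0")
    start, cross = {}, {}
    for chrom, length in layout.chromosomes:
        n_co = rng.poisson(crossover_mean)
        cross[chrom] = np.sort(rng.uniform(0, length, size=n_co))
        start[chrom] = int(rng.integers(0, 2))
    return Gamete(start, cross)


def _bin_states(layout: GenomeLayout, g1: Gamete, g2: Gamete) -> np.ndarray:
    """True state per genome-ordered bin, evaluated at bin midpoints."""
    parts = []
    for chrom, length in layout.chromosomes:
        n = layout.n_bins(chrom)
        mids = np.minimum(np.arange(n) * layout.bin_size + layout.bin_size / 2, length - 0.5)
        parts.append(g1.origin_at(chrom, mids) + g2.origin_at(chrom, mids))
    return np.concatenate(parts).astype(np.int8)


def simulate_f2_cohort(
    config: CrossSimConfig, panel: SNPPanel | None = None
) -> tuple[TrueGenotypes, AlleleCounts]:
    """Simulate the F2 cohort: genomes from paired independent F1 gametes,
    then shallow sequencing of the panel sites.

    Reads per site are Poisson(depth_mean); each read samples one of the
    two haplotypes (so a het site yields either allele with probability
    1/2) and reports the wrong allele with probability ``seq_error``.
    """
    if config.n_f2 < 1:
        raise ValueError("n_f2 must be >= 1")
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = simulate_panel(config, rng)

    layout = config.layout
    n = config.n_f2
    states = np.empty((n, layout.total_bins), dtype=np.int8)
    gametes: list[tuple[Gamete, Gamete]] = []
    # per-chromosome per-site true genotypes, filled sample by sample
    site_geno = {c: np.empty((n, panel.positions[c].size), dtype=np.int8) for c in layout.names}
    for i in range(n):
        g1 = simulate_meiosis(layout, config.crossover_mean, rng)
        g2 = simulate_meiosis(layout, config.crossover_mean, rng)
        gametes.append((g1, g2))
        states[i] = _bin_states(layout, g1, g2)
        for chrom in layout.names:
            pos = panel.positions[chrom]
            site_geno[chrom][i] = g1.origin_at(chrom, pos) + g2.origin_at(chrom, pos)

    # P(read supports Kaga allele | genotype), including the error channel
    e = config.seq_error
    p_kaga = np.array([e, 0.5, 1.0 - e])
    cab_counts, kaga_counts = {}, {}
    for chrom in layout.names:
        depth = rng.poisson(config.depth_mean, size=site_geno[chrom].shape)
        kaga_r = rng.binomial(depth, p_kaga[site_geno[chrom]])
        kaga_counts[chrom] = kaga_r.astype(np.uint16)
        cab_counts[chrom] = (depth - kaga_r).astype(np.uint16)

    sample_ids = [f"F2_{i:04d}" for i in range(n)]
    truth = TrueGenotypes(layout, states, gametes)
    counts = AlleleCounts(panel, cab_counts, kaga_counts, sample_ids)
    return truth, counts


def effect_for_pve(
    pve: float,
    dosage_var: float = 0.5,
    background_var: float = 1.0,
) -> float:
    """Additive effect size giving a QTL the requested fraction of trait
    variance.

    In an F2 the dosage at one locus is {0,1,2} with probabilities
    (1/4, 1/2, 1/4), hence variance 1/2.  Solving
    ``pve = b^2 v / (b^2 v + background_var)`` for b.
    """
    if not 0 <= pve < 1:
        raise ValueError("pve must be in [0, 1)")
    if pve == 0:
        return 0.0
    return float(np.sqrt(pve / (1 - pve) * background_var / dosage_var))


def simulate_phenotypes(
    true_geno: TrueGenotypes,
    config: CrossSimConfig,
    rng: np.random.Generator | None = None,
):
    """Quantitative trait per F2: sum of QTL effects on bin dosages, an
    additive polygenic term built from genome-wide standardised dosages,
    a per-batch additive shift, and Gaussian noise.

    Returns a pandas DataFrame (sample, value, batch, plus per-component
    columns) with the realised variance fractions in ``df.attrs``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    layout = true_geno.layout
    n = true_geno.n_samples
    offsets = layout.bin_offsets

    qtl = np.zeros(n)
    for chrom, bin_k, beta in config.qtl_spec:
        if chrom not in offsets or not 0 <= bin_k < layout.n_bins(chrom):
            raise ValueError(f"QTL bin {chrom}:{bin_k} outside layout")
        qtl += beta * true_geno.states[:, offsets[chrom] + bin_k]

    poly = np.zeros(n)
    if config.polygenic_var > 0:
        X = true_geno.states.astype(float)
        sd = X.std(axis=0)
        keep = sd > 0
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        raw = Z @ rng.standard_normal(keep.sum())
        s = raw.std()
        if s > 0:
            poly = raw * np.sqrt(config.polygenic_var) / s

    batches = sorted(config.batch_effects)
    batch_lab = np.array(batches)[rng.integers(0, len(batches), size=n)]
    batch = np.array([config.batch_effects[b] for b in batch_lab])

    eps = rng.normal(0.0, np.sqrt(config.residual_var), size=n)
    y = qtl + poly + batch + eps

    df = pd.DataFrame(
        {
            "sample": [f"F2_{i:04d}" for i in range(n)],
            "value": y,
            "batch": batch_lab,
            "qtl_component": qtl,
            "polygenic_component": poly,
            "batch_component": batch,
            "residual_component": eps,
        }
    )
    tot = y.var() if n > 1 else np.nan
    df.attrs["variance_fractions"] = {
        "qtl": float(qtl.var() / tot) if tot else np.nan,
        "polygenic": float(poly.var() / tot) if tot else np.nan,
        "residual": float(eps.var() / tot) if tot else np.nan,
    }
    return df


def simulate_oscillation(
    period_min: float,
    amplitude: float = 1.0,
    trend_slope: float = 0.0,
    envelope_rate: float = 0.0,
    noise_sd: float = 0.0,
    duration_min: float = 600.0,
    interval_min: float = 10.0,
    rng: np.random.Generator | None = None,
) -> OscillationTrace:
    """Synthetic reporter trace: exponentially enveloped sinusoid plus
    linear trend plus white noise, sampled every ``interval_min`` minutes
    over ``[0, duration_min]`` inclusive."""
    if period_min <= 0:
        raise ValueError("period must be positive")
    if duration_min < 2 * interval_min:
        raise ValueError("duration must cover at least two sampling intervals")
    rng = np.random.default_rng(0) if rng is None else rng
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    x = (
        amplitude * np.exp(envelope_rate * t) * np.sin(2 * np.pi * t / period_min)
        + trend_slope * t
        + rng.normal(0.0, noise_sd, size=t.size)
    )
    return OscillationTrace(interval_min, x, true_period_min=period_min)
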