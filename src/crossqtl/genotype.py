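"""Low-coverage F2 genotyping from binned allele-read frequencies.

Reads supporting either parental allele are summed within non-overlapping
5-kb bins; the per-bin fraction of Kaga-supporting reads (empty bins fixed
at 0.5) is decoded chromosome-by-chromosome with a 3-state Gaussian HMM
(state means 0, 0.5, 1; shared emission variance 0.8; off-diagonal
transition probability near zero).  The near-zero transitions make the
most-probable path a small number of long recombination blocks, matching
the expectation of under one crossover per chromosome per meiosis.  Bins
without any panel SNP are never decoded; after decoding they are filled
from the previous called bin (or, at a chromosome start, the next one).
Filled per-bin states double as "pseudo-SNP" dosages for association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, SNPPanel
from .simulate import AlleleCounts

STATE_NAMES = ("hom_cab", "het", "hom_kaga")


@dataclass
class HMMSpec:
    """Fixed (untrained) parameters of the 3-state genotype HMM."""

    means: tuple[float, float, float] = (0.0, 0.5, 1.0)
    emission_var: float = 0.8
    trans_prob: float = 1e-8
    start_prob: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.emission_var <= 0:
            raise ValueError("emission variance must be positive")
        if not 0 <= self.trans_prob < 0.5:
            raise ValueError("off-diagonal transition probability must be in [0, 0.5)")
        if abs(sum(self.start_prob) - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")

    @property
    def transmat(self) -> np.ndarray:
        t = np.full((3, 3), self.trans_prob)
        np.fill_diagonal(t, 1.0 - 2.0 * self.trans_prob)
        return t


@dataclass
class BinFrequencies:
    """Per-sample, per-bin Kaga-allele read fraction for a cohort.

    ``freq`` is (n_samples, total_bins) in genome bin order; bins with zero
    reads hold exactly 0.5.  ``snp_count`` marks which bins contain panel
    SNPs at all — bins without any are "missing" and never decoded.
    """

    layout: GenomeLayout
    sample_ids: list[str]
    freq: np.ndarray  # float64 in [0, 1]
    reads: np.ndarray  # int64 total reads per bin
    snp_count: np.ndarray  # (total_bins,) panel SNPs per bin

    @property
    def missing_bins(self) -> np.ndarray:
        return self.snp_count == 0

    def informative_fraction(self) -> np.ndarray:
        """Per sample, fraction of bins with at least one read."""
        return (self.reads > 0).mean(axis=1)


@dataclass
class GenotypeCalls:
    """Cohort per-bin states in {0,1,2}; -1 marks missing before filling."""

    layout: GenomeLayout
    sample_ids: list[str]
    states: np.ndarray  # (n_samples, total_bins) int8
    missing: np.ndarray  # (total_bins,) bool — bins with no panel SNPs
    filled: np.ndarray = field(default=None)  # (total_bins,) bool

    def __post_init__(self) -> None:
        if self.filled is None:
            self.filled = np.zeros(self.layout.total_bins, dtype=bool)

    def per_chromosome(self, sample: int):
        offsets = self.layout.bin_offsets
        for chrom in self.layout.names:
            o = offsets[chrom]
            yield chrom, self.states[sample, o : o + self.layout.n_bins(chrom)]


@dataclass
class PseudoSNPMatrix:
    """Samples x bins dosage matrix (count of Kaga-type alleles, 0/1/2)."""

    sample_ids: list[str]
    bin_ids: list[str]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    dosages: np.ndarray  # (n_samples, n_bins) int8
    monomorphic: np.ndarray  # (n_bins,) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


def bin_allele_counts(
    counts: AlleleCounts, panel: SNPPanel, layout: GenomeLayout
) -> BinFrequencies:
    """Sum per-SNP reads within bins and form the Kaga-allele fraction.

    Bins containing no reads are assigned exactly 0.5.
    """
    n = counts.n_samples
    B = layout.total_bins
    cab_tot = np.zeros((n, B))
    kaga_tot = np.zeros((n, B))
    offsets = layout.bin_offsets
    for chrom in layout.names:
        pos = panel.positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        if pos[-1] >= layout.length(chrom):
            raise ValueError(f"panel site outside chromosome {chrom} (layout mismatch)")
        bin_idx = offsets[chrom] + pos // layout.bin_size
        # sites are position-sorted, so bins are contiguous runs
        edges = np.flatnonzero(np.r_[True, np.diff(bin_idx) > 0])
        uniq = bin_idx[edges]
        cab_tot[:, uniq] += np.add.reduceat(counts.cab[chrom].astype(np.int64), edges, axis=1)
        kaga_tot[:, uniq] += np.add.reduceat(counts.kaga[chrom].astype(np.int64), edges, axis=1)
    total = cab_tot + kaga_tot
    freq = np.full((n, B), 0.5)
    nz = total > 0
    freq[nz] = kaga_tot[nz] / total[nz]
    return BinFrequencies(
        layout=layout,
        sample_ids=list(counts.sample_ids),
        freq=freq,
        reads=total.astype(np.int64),
        snp_count=panel.sites_per_bin(),
    )


def _viterbi_batch(obs: np.ndarray, spec: HMMSpec) -> np.ndarray:
    """Most-probable state paths for a batch of equal-length sequences.

    ``obs`` is (n_sequences, T); returns (n_sequences, T) int8.  Log-space
    dynamic programming vectorised over the sequence axis.
    """
    n, T = obs.shape
    means = np.asarray(spec.means)
    var = spec.emission_var
    # (n, T, 3) Gaussian log-density up to the shared normalising constant
    ll = -0.5 * (obs[:, :, None] - means) ** 2 / var
    log_start = np.log(np.asarray(spec.start_prob))
    log_trans = np.log(spec.transmat)  # (3, 3)

    back = np.empty((n, T, 3), dtype=np.int8)
    delta = log_start + ll[:, 0, :]
    for t in range(1, T):
        cand = delta[:, :, None] + log_trans[None, :, :]  # (n, prev, next)
        back[:, t, :] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + ll[:, t, :]
    path = np.empty((n, T), dtype=np.int8)
    path[:, -1] = np.argmax(delta, axis=1)
    rows = np.arange(n)
    for t in range(T - 2, -1, -1):
        path[:, t] = back[rows, t + 1, path[:, t + 1]]
    return path


def decode_genotypes(freqs: BinFrequencies, spec: HMMSpec | None = None) -> GenotypeCalls:
    """Viterbi-decode each chromosome of each sample into genotype states.

    Bins without panel SNPs are excluded from the decoded sequence and
    flagged missing (state -1) for the filling step.
    """
    spec = HMMSpec() if spec is None else spec
    layout = freqs.layout
    missing = freqs.missing_bins
    states = np.full(freqs.freq.shape, -1, dtype=np.int8)
    offsets = layout.bin_offsets
    for chrom in layout.names:
        o = offsets[chrom]
        nb = layout.n_bins(chrom)
        keep = ~missing[o : o + nb]
        if not keep.any():
            raise ValueError(f"chromosome {chrom} has no bins with panel SNPs")
        obs = freqs.freq[:, o : o + nb][:, keep]
        states[:, o : o + nb][:, keep] = _viterbi_batch(obs, spec)
    return GenotypeCalls(layout, list(freqs.sample_ids), states, missing.copy())


def fill_missing(calls: GenotypeCalls) -> GenotypeCalls:
    """Impute missing bins from the previous called bin on the chromosome,
    or — for a leading gap — from the next called bin."""
    layout = calls.layout
    states = calls.states.copy()
    filled = np.zeros(layout.total_bins, dtype=bool)
    offsets = layout.bin_offsets
    for chrom in layout.names:
        o = offsets[chrom]
        nb = layout.n_bins(chrom)
        sl = slice(o, o + nb)
        miss = calls.missing[sl]
        if miss.all():
            raise ValueError(f"chromosome {chrom} entirely missing; cannot fill")
        if not miss.any():
            continue
        filled[sl] = miss
        idx = np.arange(nb)
        prev = np.where(miss, -1, idx)
        prev = np.maximum.accumulate(prev)  # last called index at or before k
        nxt = np.where(miss, nb, idx)[::-1]
        nxt = np.minimum.accumulate(nxt)[::-1]  # first called index at or after k
        source = np.where(prev >= 0, prev, nxt)
        states[:, sl] = states[:, sl][:, source]
    out = GenotypeCalls(layout, list(calls.sample_ids), states, calls.missing.copy())
    out.filled = filled
    return out


def qc_samples(
    freqs: BinFrequencies, min_informative_fraction: float = 0.5
) -> tuple[list[str], list[str], np.ndarray]:
    """Split samples by genome-wide coverage.

    A sample is kept when the fraction of bins with at least one read is at
    least the threshold; mirrors excluding samples with poor coverage
    across the genome.  Returns (kept ids, excluded ids, fractions).
    """
    if not 0 <= min_informative_fraction <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if not freqs.sample_ids:
        raise ValueError("empty cohort")
    frac = freqs.informative_fraction()
    kept = [s for s, f in zip(freqs.sample_ids, frac) if f >= min_informative_fraction]
    excl = [s for s, f in zip(freqs.sample_ids, frac) if f < min_informative_fraction]
    return kept, excl, frac


def build_pseudosnps(calls: GenotypeCalls, drop_monomorphic: bool = False) -> PseudoSNPMatrix:
    """Treat every filled 5-kb genotype bin as a biallelic marker whose
    dosage is the state code (count of Kaga-type alleles)."""
    if np.any(calls.states < 0):
        raise ValueError("calls contain missing states; run fill_missing first")
    layout = calls.layout
    chrom, start, end = layout.bin_table()
    dos = calls.states.astype(np.int8)
    mono = np.all(dos == dos[0], axis=0)
    bin_ids = layout.bin_ids()
    if drop_monomorphic:
        keep = ~mono
        chrom, start, end, dos = chrom[keep], start[keep], end[keep], dos[:, keep]
        bin_ids = [b for b, k in zip(bin_ids, keep) if k]
        mono = mono[keep]
    return PseudoSNPMatrix(
        sample_ids=list(calls.sample_ids),
        bin_ids=bin_ids,
        chrom=chrom,
        start=start,
        end=end,
        dosages=dos,
        monomorphic=mono,
    )


def count_state_changes(calls: GenotypeCalls) -> np.ndarray:
    """Adjacent-bin state changes per chromosome per sample.

    Returns (n_samples, n_chromosomes); a decoded F2 chromosome is expected
    to change state only a handful of times when crossovers average under
    one per chromosome per meiosis.
    """
    layout = calls.layout
    offsets = layout.bin_offsets
    out = np.zeros((calls.states.shape[0], len(layout.names)), dtype=np.int64)
    for j, chrom in enumerate(layout.names):
        o = offsets[chrom]
        seg = calls.states[:, o : o + layout.n_bins(chrom)]
        out[:, j] = (np.diff(seg, axis=1) != 0).sum(axis=1)
    return out
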