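"""Genome layout and marker-panel containers.

The genotyping model works on non-overlapping fixed-width bins (default
5 kb) tiled across each chromosome; the informative markers are biallelic
SNPs at which the two inbred parental strains are homozygous for different
alleles, so every F1 is heterozygous and every F2 genotype is one of
{hom-parent-A, het, hom-parent-B}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the genotyping bin width.

    Bin ``k`` of a chromosome spans ``[k*bin_size, (k+1)*bin_size)`` in
    0-based half-open coordinates; the last bin may be short.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 5000

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)

    @property
    def bins_per_chrom(self) -> dict[str, int]:
        return {name: self.n_bins(name) for name in self.names}

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(name) for name in self.names)

    @property
    def bin_offsets(self) -> dict[str, int]:
        """Global (genome-wide, concatenated) index of each chromosome's bin 0."""
        out, acc = {}, 0
        for name in self.names:
            out[name] = acc
            acc += self.n_bins(name)
        return out

    def bin_index(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Map base-pair position(s) to within-chromosome bin index."""
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= self.length(chrom)):
            raise ValueError(f"position outside chromosome {chrom}")
        return pos // self.bin_size

    def bin_ids(self) -> list[str]:
        """Genome-ordered ``chrom:start-end`` labels, one per bin."""
        out = []
        for name, length in self.chromosomes:
            for k in range(self.n_bins(name)):
                start = k * self.bin_size
                out.append(f"{name}:{start}-{min(start + self.bin_size, length)}")
        return out

    def bin_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (chrom, start, end) over genome-ordered bins."""
        chroms, starts, ends = [], [], []
        for name, length in self.chromosomes:
            n = self.n_bins(name)
            ks = np.arange(n)
            chroms.append(np.full(n, name, dtype=object))
            starts.append(ks * self.bin_size)
            ends.append(np.minimum((ks + 1) * self.bin_size, length))
        return (
            np.concatenate(chroms),
            np.concatenate(starts).astype(np.int64),
            np.concatenate(ends).astype(np.int64),
        )


@dataclass
class SNPPanel:
    """Homozygous-divergent biallelic sites: positions plus parental alleles.

    ``positions[chrom]`` is strictly increasing (0-based bp).  At every site
    parent A ("Cab-type") and parent B ("Kaga-type") carry different alleles,
    so read support for either allele is fully informative about haplotype
    origin.
    """

    layout: GenomeLayout
    positions: dict[str, np.ndarray]
    cab_allele: dict[str, np.ndarray] = field(default_factory=dict)
    kaga_allele: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if pos.size and (pos[0] < 0 or pos[-1] >= self.layout.length(chrom)):
                raise ValueError(f"position outside chromosome {chrom}")
            if chrom not in self.cab_allele:
                self.cab_allele[chrom] = np.full(pos.size, "A", dtype="U1")
                self.kaga_allele[chrom] = np.full(pos.size, "T", dtype="U1")
            same = self.cab_allele[chrom] == self.kaga_allele[chrom]
            if np.any(same):
                raise ValueError(f"non-divergent site on {chrom}")

    @property
    def n_sites(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def sites_per_bin(self) -> np.ndarray:
        """Number of panel SNPs in each genome-ordered bin."""
        counts = np.zeros(self.layout.total_bins, dtype=np.int64)
        offsets = self.layout.bin_offsets
        for chrom in self.layout.names:
            pos = self.positions.get(chrom, np.empty(0, dtype=np.int64))
            if pos.size:
                idx = offsets[chrom] + pos // self.layout.bin_size
                np.add.at(counts, idx, 1)
        return counts


def random_divergent_alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` pairs of distinct nucleotides (parent-A allele, parent-B allele)."""
    a = rng.integers(0, 4, size=n)
    b = (a + rng.integers(1, 4, size=n)) % 4
    return _NUCS[a], _NUCS[b]
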