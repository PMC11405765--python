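"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab- or comma-separated text: SNP panels (TSV and a minimal
two-sample VCF), per-SNP allele counts, per-sample recombination blocks
(BED), the pseudo-SNP dosage matrix, trait tables, oscillation traces and
association output.  The same dialects accepted here for simulated data
would be produced from real data by upstream read counting.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import GenomeLayout, SNPPanel
from .genotype import BinFrequencies, GenotypeCalls, PseudoSNPMatrix
from .simulate import AlleleCounts


# -- layout ------------------------------------------------------------------

def write_layout(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tbin_size\n")
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\t{layout.bin_size}\n")


def read_layout(path: str) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    return GenomeLayout(
        chromosomes=tuple(zip(df["chrom"], df["length"].astype(int))),
        bin_size=int(df["bin_size"].iloc[0]),
    )


# -- SNP panel ---------------------------------------------------------------

def write_panel_tsv(panel: SNPPanel, path: str) -> None:
    rows = []
    for chrom in panel.layout.names:
        pos = panel.positions.get(chrom)
        if pos is None:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "cab_allele": panel.cab_allele[chrom],
                    "kaga_allele": panel.kaga_allele[chrom],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str, layout: GenomeLayout) -> SNPPanel:
    df = pd.read_csv(path, sep="\t")
    positions, cab, kaga = {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)
        cab[chrom] = grp["cab_allele"].to_numpy(dtype="U1")
        kaga[chrom] = grp["kaga_allele"].to_numpy(dtype="U1")
    return SNPPanel(layout, positions, cab, kaga)


def write_panel_vcf(panel: SNPPanel, path: str) -> None:
    """Minimal VCFv4.2 with the two parents as samples: Cab homozygous REF,
    Kaga homozygous ALT at every panel site (positions are 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in panel.layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCab\tKaga\n")
        for chrom in panel.layout.names:
            pos = panel.positions.get(chrom)
            if pos is None:
                continue
            for p, ref, alt in zip(pos, panel.cab_allele[chrom], panel.kaga_allele[chrom]):
                fh.write(f"{chrom}\t{p + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/0\t1/1\n")


def read_panel_vcf(path: str, layout: GenomeLayout) -> SNPPanel:
    """Read a panel VCF with cyvcf2, keeping biallelic SNPs at which the
    two samples (first = Cab-type) are homozygous for different alleles."""
    from cyvcf2 import VCF

    positions: dict[str, list[int]] = {}
    cab: dict[str, list[str]] = {}
    kaga: dict[str, list[str]] = {}
    vcf = VCF(path)
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        g_cab, g_kaga = var.genotypes[0][:2], var.genotypes[1][:2]
        if g_cab[0] != g_cab[1] or g_kaga[0] != g_kaga[1] or g_cab[0] == g_kaga[0]:
            continue
        alleles = [var.REF, var.ALT[0]]
        positions.setdefault(var.CHROM, []).append(var.POS - 1)
        cab.setdefault(var.CHROM, []).append(alleles[g_cab[0]])
        kaga.setdefault(var.CHROM, []).append(alleles[g_kaga[0]])
    vcf.close()
    return SNPPanel(
        layout,
        {c: np.asarray(v, dtype=np.int64) for c, v in positions.items()},
        {c: np.asarray(v, dtype="U1") for c, v in cab.items()},
        {c: np.asarray(v, dtype="U1") for c, v in kaga.items()},
    )


# -- allele counts -----------------------------------------------------------

def write_allele_counts(counts: AlleleCounts, path: str) -> None:
    """Long-format TSV (sample, chrom, pos, cab_reads, kaga_reads); zero-zero
    rows are kept so depth is recoverable."""
    panel = counts.panel
    frames = []
    for chrom in panel.layout.names:
        pos = panel.positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        for i, sid in enumerate(counts.sample_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sid,
                        "chrom": chrom,
                        "pos": pos,
                        "cab_reads": counts.cab[chrom][i],
                        "kaga_reads": counts.kaga[chrom][i],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str, panel: SNPPanel) -> AlleleCounts:
    df = pd.read_csv(path, sep="\t")
    sample_ids = list(dict.fromkeys(df["sample"]))
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    cab, kaga = {}, {}
    for chrom in panel.layout.names:
        pos = panel.positions.get(chrom, np.empty(0, dtype=np.int64))
        cab[chrom] = np.zeros((len(sample_ids), pos.size), dtype=np.uint16)
        kaga[chrom] = np.zeros((len(sample_ids), pos.size), dtype=np.uint16)
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        col = np.searchsorted(pos, sub["pos"].to_numpy())
        if np.any(col >= pos.size) or np.any(pos[np.minimum(col, pos.size - 1)] != sub["pos"].to_numpy()):
            raise ValueError(f"allele-count site not in panel on {chrom}")
        row = np.array([s_idx[s] for s in sub["sample"]])
        cab[chrom][row, col] = sub["cab_reads"].to_numpy()
        kaga[chrom][row, col] = sub["kaga_reads"].to_numpy()
    return AlleleCounts(panel, cab, kaga, sample_ids)


# -- genotype calls ----------------------------------------------------------

def write_blocks_bed(calls: GenotypeCalls, out_dir: str) -> list[str]:
    """Per-sample BED of recombination blocks: contiguous same-state runs
    (chrom, start, end, state, n_filled_bins)."""
    os.makedirs(out_dir, exist_ok=True)
    layout = calls.layout
    offsets = layout.bin_offsets
    paths = []
    for i, sid in enumerate(calls.sample_ids):
        path = os.path.join(out_dir, f"{sid}.blocks.bed")
        with open(path, "w") as fh:
            for chrom in layout.names:
                o = offsets[chrom]
                nb = layout.n_bins(chrom)
                st = calls.states[i, o : o + nb]
                fl = calls.filled[o : o + nb]
                edges = np.r_[0, np.flatnonzero(np.diff(st) != 0) + 1, nb]
                for a, b in zip(edges[:-1], edges[1:]):
                    start = int(a) * layout.bin_size
                    end = min(int(b) * layout.bin_size, layout.length(chrom))
                    fh.write(f"{chrom}\t{start}\t{end}\t{int(st[a])}\t{int(fl[a:b].sum())}\n")
        paths.append(path)
    return paths


def write_frequencies(freqs: BinFrequencies, path: str) -> None:
    bin_ids = freqs.layout.bin_ids()
    df = pd.DataFrame(freqs.freq, index=pd.Index(freqs.sample_ids, name="sample"), columns=bin_ids)
    df.to_csv(path, sep="\t")


def write_pseudosnps(mat: PseudoSNPMatrix, path: str) -> None:
    df = pd.DataFrame(mat.dosages, index=pd.Index(mat.sample_ids, name="sample"), columns=mat.bin_ids)
    df.to_csv(path, sep="\t")


def read_pseudosnps(path: str) -> PseudoSNPMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    bin_ids = list(df.columns)
    chrom = np.array([b.split(":")[0] for b in bin_ids], dtype=object)
    spans = [b.split(":")[1].split("-") for b in bin_ids]
    start = np.array([int(s[0]) for s in spans], dtype=np.int64)
    end = np.array([int(s[1]) for s in spans], dtype=np.int64)
    dos = df.to_numpy(dtype=np.int8)
    return PseudoSNPMatrix(
        sample_ids=list(df.index),
        bin_ids=bin_ids,
        chrom=chrom,
        start=start,
        end=end,
        dosages=dos,
        monomorphic=np.all(dos == dos[0], axis=0),
    )


# -- traits, traces, association ---------------------------------------------

def write_traits(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_traits(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trace_csv(trace, path: str) -> None:
    pd.DataFrame({"time_min": trace.times, "intensity": trace.values}).to_csv(path, index=False)


def read_trace_csv(path: str):
    from .simulate import OscillationTrace

    df = pd.read_csv(path)
    t = df["time_min"].to_numpy(dtype=float)
    dt = float(np.diff(t).mean()) if t.size > 1 else 10.0
    if t.size > 1 and not np.allclose(np.diff(t), dt):
        raise ValueError("trace is not evenly sampled")
    return OscillationTrace(dt, df["intensity"].to_numpy(dtype=float))


def write_association(scan: pd.DataFrame, path: str) -> None:
    scan.to_csv(path, sep="\t", index=False)
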