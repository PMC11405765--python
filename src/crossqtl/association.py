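"""Pseudo-SNP association mapping with a LOCO linear mixed model.

Each filled 5-kb genotype bin is a marker ("pseudo-SNP") with dosage
0/1/2.  The model per tested marker is

    y = W a + x b + g + e,   g ~ N(0, s2_g * G),  e ~ N(0, s2_e * I)

where G is the genetic relationship matrix computed from all markers NOT
on the tested marker's chromosome (leave-one-chromosome-out, avoiding
proximal contamination).  Variance components are estimated once per LOCO
GRM by profile REML on the eigendecomposition of G; each marker then gets
a 1-df Wald chi-square for b with the variance ratio held at the null
estimate and the residual scale re-estimated per marker (FaST-LMM style).

Genome-wide significance follows the permutation scheme: the phenotype
(with covariates, jointly) is permuted across samples with 10 distinct
seeds, a full scan is run per permutation, and the smallest p-value seen
anywhere becomes the threshold; a Bonferroni threshold 0.05 / n_markers is
kept as a secondary line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .genotype import PseudoSNPMatrix


@dataclass
class GRM:
    """Genetic relationship matrix plus its provenance."""

    matrix: np.ndarray
    n_markers: int
    excluded_chrom: str | None = None
    n_monomorphic: int = 0
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values, vectors)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig


@dataclass
class NullModelFit:
    """REML fit of the no-marker mixed model."""

    sigma2_g: float
    sigma2_e: float
    log_likelihood: float
    ratio: float  # s2_g / s2_e
    heritability: float


def _standardized_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GCTA-style standardisation: (x - 2p)/sqrt(2p(1-p)) at polymorphic
    markers, allele frequency p estimated from the sample."""
    X = np.asarray(dosages, dtype=float)
    p = X.mean(axis=0) / 2.0
    # a constant column (e.g. all-het) is monomorphic even at 0 < p < 1
    poly = (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    Z = (X[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    return Z, poly


def compute_grm(pseudosnps: PseudoSNPMatrix, exclude_chrom: str | None = None) -> GRM:
    """G_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i))
    over polymorphic markers, optionally excluding one chromosome."""
    n = pseudosnps.shape[0]
    if n < 2:
        raise ValueError("GRM needs at least 2 samples")
    mask = np.ones(pseudosnps.shape[1], dtype=bool)
    if exclude_chrom is not None:
        on = pseudosnps.chrom == exclude_chrom
        if not on.any():
            raise ValueError(f"no markers on chromosome {exclude_chrom!r}")
        mask = ~on
    Z, poly = _standardized_dosages(pseudosnps.dosages[:, mask])
    M = Z.shape[1]
    if M == 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    return GRM(
        matrix=Z @ Z.T / M,
        n_markers=M,
        excluded_chrom=exclude_chrom,
        n_monomorphic=int((~poly).sum()),
    )


def loco_grm(pseudosnps: PseudoSNPMatrix, chromosome: str) -> GRM:
    """Leave-one-chromosome-out GRM for markers tested on ``chromosome``."""
    if len(set(pseudosnps.chrom)) < 2:
        raise ValueError("LOCO needs at least 2 chromosomes")
    return compute_grm(pseudosnps, exclude_chrom=chromosome)


def _reml_neg_loglik(log_ratio: float, yt: np.ndarray, Wt: np.ndarray, S: np.ndarray) -> float:
    lam = np.exp(log_ratio)
    d = lam * S + 1.0
    w = 1.0 / d
    WtW = Wt.T @ (w[:, None] * Wt)
    Wty = Wt.T @ (w * yt)
    beta = np.linalg.solve(WtW, Wty)
    rss = float(np.sum(w * (yt - Wt @ beta) ** 2))
    n, p = yt.size, Wt.shape[1]
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + (n - p)
        + np.sum(np.log(d))
        + np.linalg.slogdet(WtW)[1]
    )
    return -ll


def fit_null_lmm(
    phenotype: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
) -> NullModelFit:
    """Profile-REML variance components on the GRM eigendecomposition.

    The single free parameter is the ratio lambda = s2_g/s2_e, optimised
    on a log grid refined by bounded scalar minimisation; s2_e is profiled
    out in closed form.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if grm.matrix.shape != (n, n):
        raise ValueError("phenotype length does not match GRM dimension")
    if np.isnan(y).any():
        raise ValueError("drop missing phenotypes before fitting")
    W = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    S, U = grm.eig()
    if not np.all(np.isfinite(S)):
        raise np.linalg.LinAlgError("GRM eigendecomposition failed (non-finite spectrum)")
    yt, Wt = U.T @ y, U.T @ W

    grid = np.linspace(-8.0, 8.0, 33)
    vals = [_reml_neg_loglik(g, yt, Wt, S) for g in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, args=(yt, Wt, S), bounds=(lo, hi), method="bounded"
    )
    # allow the boundary solution lambda -> 0 when the grid prefers it
    candidates = [(res.fun, float(np.exp(res.x))), (_reml_neg_loglik(-30.0, yt, Wt, S), 0.0)]
    negll, lam = min(candidates, key=lambda t: t[0])

    d = lam * S + 1.0
    w = 1.0 / d
    WtW = Wt.T @ (w[:, None] * Wt)
    beta = np.linalg.solve(WtW, Wt.T @ (w * yt))
    rss = float(np.sum(w * (yt - Wt @ beta) ** 2))
    sigma2_e = rss / (n - W.shape[1])
    sigma2_g = lam * sigma2_e
    h2 = sigma2_g / (sigma2_g + sigma2_e) if sigma2_g + sigma2_e > 0 else 0.0
    return NullModelFit(sigma2_g, sigma2_e, -negll, lam, h2)


def _scan_chromosome(
    yt: np.ndarray,
    Wt: np.ndarray,
    Xt: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wald tests for each column of Xt added to the weighted null model.

    Residualises y and every marker against the covariates under the GLS
    weights (Frisch-Waugh), then closes the 1-df test in vectorised form.
    Returns (beta, se, chisq, p); monomorphic columns get p = 1.
    """
    n, p = Wt.shape
    w = weights
    WtW = Wt.T @ (w[:, None] * Wt)

    def resid(v):
        coef = np.linalg.solve(WtW, Wt.T @ (w[:, None] * v) if v.ndim > 1 else Wt.T @ (w * v))
        return v - Wt @ coef

    ry = resid(yt)
    rX = resid(Xt)
    sxx = np.einsum("i,ij,ij->j", w, rX, rX)
    sxy = np.einsum("i,ij,i->j", w, rX, ry)
    syy = float(np.sum(w * ry * ry))
    ok = sxx > 1e-12 * max(float(sxx.max(initial=0.0)), 1.0)
    beta = np.zeros(Xt.shape[1])
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta * sxy
    dof = n - p - 1
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.full(Xt.shape[1], np.nan)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
    chisq = np.zeros(Xt.shape[1])
    chisq[ok] = (beta[ok] / se[ok]) ** 2
    pvals = np.ones(Xt.shape[1])
    pvals[ok] = chi2.sf(chisq[ok], df=1)
    return beta, se, chisq, pvals


def association_scan(
    phenotype: np.ndarray,
    pseudosnps: PseudoSNPMatrix,
    loco_grms: dict[str, GRM] | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """LOCO mixed-model scan over every pseudo-SNP.

    Returns a genome-ordered DataFrame (chrom, start, end, bin_id, beta,
    se, chisq, p, monomorphic).  ``loco_grms`` may be precomputed (and is
    reused across permutations); otherwise it is built here.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.size != pseudosnps.shape[0]:
        raise ValueError("phenotype length does not match sample count")
    chroms = list(dict.fromkeys(pseudosnps.chrom))
    if loco_grms is None:
        loco_grms = {c: loco_grm(pseudosnps, c) for c in chroms}
    n = y.size
    W = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])

    out = {k: [] for k in ("beta", "se", "chisq", "p")}
    for c in chroms:
        grm = loco_grms[c]
        null = fit_null_lmm(y, grm, covariates)
        S, U = grm.eig()
        weights = 1.0 / (null.ratio * S + 1.0)
        on = pseudosnps.chrom == c
        Xt = U.T @ pseudosnps.dosages[:, on].astype(float)
        beta, se, chisq, pvals = _scan_chromosome(U.T @ y, U.T @ W, Xt, weights)
        for k, v in zip(("beta", "se", "chisq", "p"), (beta, se, chisq, pvals)):
            out[k].append(v)

    order = np.concatenate([np.flatnonzero(pseudosnps.chrom == c) for c in chroms])
    df = pd.DataFrame(
        {
            "chrom": pseudosnps.chrom[order],
            "start": pseudosnps.start[order],
            "end": pseudosnps.end[order],
            "bin_id": np.asarray(pseudosnps.bin_ids, dtype=object)[order],
            "beta": np.concatenate(out["beta"]),
            "se": np.concatenate(out["se"]),
            "chisq": np.concatenate(out["chisq"]),
            "p": np.concatenate(out["p"]),
        }
    )
    df["monomorphic"] = pseudosnps.monomorphic[order]
    if not np.array_equal(order, np.arange(order.size)):
        df = df.iloc[np.argsort(order, kind="stable")].reset_index(drop=True)
    return df


def permutation_threshold(
    phenotype: np.ndarray,
    pseudosnps: PseudoSNPMatrix,
    loco_grms: dict[str, GRM] | None = None,
    covariates: np.ndarray | None = None,
    n_perm: int = 10,
    seeds: list[int] | None = None,
) -> tuple[float, list[float]]:
    """Permutation genome-wide significance threshold.

    Rows of (phenotype, covariates) are permuted jointly against the
    genotypes once per seed; the threshold is the single smallest p-value
    over all permutations and markers.  Returns (threshold,
    per-permutation minima).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if seeds is None:
        seeds = list(range(n_perm))
    if len(seeds) != n_perm or len(set(seeds)) != n_perm:
        raise ValueError("seeds must be distinct and match n_perm")
    y = np.asarray(phenotype, dtype=float)
    chroms = list(dict.fromkeys(pseudosnps.chrom))
    if loco_grms is None:
        loco_grms = {c: loco_grm(pseudosnps, c) for c in chroms}
    minima = []
    for s in seeds:
        perm = np.random.default_rng(s).permutation(y.size)
        cov = None if covariates is None else np.asarray(covariates)[perm]
        scan = association_scan(y[perm], pseudosnps, loco_grms, cov)
        minima.append(float(scan["p"].min()))
    return min(minima), minima


def bonferroni_threshold(n_pseudosnps: int, alpha: float = 0.05) -> float:
    """alpha divided by the number of pseudo-SNPs in the model."""
    if n_pseudosnps < 1:
        raise ValueError("need at least one pseudo-SNP")
    return alpha / n_pseudosnps


def call_significant(
    scan: pd.DataFrame,
    perm_threshold: float,
    bonf_threshold: float | None = None,
) -> pd.DataFrame:
    """Flag markers below each threshold and merge contiguous significant
    bins (same chromosome, adjacent coordinates) into loci.

    Returns one row per locus: chrom, start, end, n_bins, peak bin and its
    p-value, and which thresholds the locus clears.
    """
    scan = scan.copy()
    scan["sig_perm"] = scan["p"] < perm_threshold
    scan["sig_bonf"] = (scan["p"] < bonf_threshold) if bonf_threshold is not None else False
    sig = scan[scan["sig_perm"] | scan["sig_bonf"]]
    loci = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        breaks = np.flatnonzero(grp["start"].to_numpy()[1:] != grp["end"].to_numpy()[:-1])
        bounds = np.r_[0, breaks + 1, len(grp)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = grp.iloc[a:b]
            peak = block.loc[block["p"].idxmin()]
            loci.append(
                {
                    "chrom": chrom,
                    "start": int(block["start"].min()),
                    "end": int(block["end"].max()),
                    "n_bins": len(block),
                    "peak_bin": peak["bin_id"],
                    "peak_start": int(peak["start"]),
                    "peak_p": float(peak["p"]),
                    "sig_perm": bool(block["sig_perm"].any()),
                    "sig_bonf": bool(block["sig_bonf"].any()),
                }
            )
    return pd.DataFrame(
        loci,
        columns=[
            "chrom", "start", "end", "n_bins", "peak_bin",
            "peak_start", "peak_p", "sig_perm", "sig_bonf",
        ],
    )
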