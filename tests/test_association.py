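import numpy as np
import pandas as pd
import pytest

from crossqtl import (
    CrossSimConfig,
    GenomeLayout,
    association_scan,
    bonferroni_threshold,
    build_pseudosnps,
    call_significant,
    compute_grm,
    effect_for_pve,
    fit_null_lmm,
    loco_grm,
    permutation_threshold,
    simulate_f2_cohort,
    simulate_phenotypes,
)
from crossqtl.association import GRM
from crossqtl.genotype import GenotypeCalls, PseudoSNPMatrix


def _pseudo_from_dosages(dosages, n_chrom=1):
    """Wrap a raw dosage matrix as pseudo-SNPs split evenly over chromosomes."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    per = m // n_chrom
    chrom = np.concatenate(
        [np.full(per if c < n_chrom - 1 else m - per * (n_chrom - 1), f"chr{c + 1}", dtype=object)
         for c in range(n_chrom)]
    )
    start = np.concatenate([np.arange((chrom == f"chr{c + 1}").sum()) * 5000 for c in range(n_chrom)])
    end = start + 5000
    bin_ids = [f"{c}:{s}-{e}" for c, s, e in zip(chrom, start, end)]
    return PseudoSNPMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        bin_ids=bin_ids,
        chrom=chrom,
        start=start.astype(np.int64),
        end=end.astype(np.int64),
        dosages=dosages,
        monomorphic=np.all(dosages == dosages[0], axis=0),
    )


def _naive_grm(dosages):
    """Double-loop GCTA GRM, the independent oracle."""
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X, p = X[:, keep], p[keep]
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            G[j, k] = np.mean((X[j] - 2 * p) * (X[k] - 2 * p) / (2 * p * (1 - p)))
    return G


class TestComputeGrm:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(20, 200))
        grm = compute_grm(_pseudo_from_dosages(dosages))
        np.testing.assert_allclose(grm.matrix, _naive_grm(dosages), atol=1e-10)

    def test_identical_samples_have_equal_relatedness_entries(self):
        row = np.random.default_rng(1).integers(0, 3, size=300)
        dosages = np.vstack([row, row, 2 - row])
        grm = compute_grm(_pseudo_from_dosages(dosages))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[1, 1])

    def test_independent_dosages_give_near_zero_offdiagonal(self):
        rng = np.random.default_rng(2)
        dosages = rng.binomial(2, 0.5, size=(100, 5000))
        grm = compute_grm(_pseudo_from_dosages(dosages))
        off = grm.matrix[~np.eye(100, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_f2_cohort_diagonal_near_one(self, desk_pseudosnps):
        grm = compute_grm(desk_pseudosnps)
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.1

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(_pseudo_from_dosages(np.ones((5, 10), dtype=int)))


class TestLocoGrm:
    def test_excludes_tested_chromosome_markers(self):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, 0.5, size=(30, 500))
        pseudo = _pseudo_from_dosages(dosages, n_chrom=5)
        grm = loco_grm(pseudo, "chr2")
        assert grm.n_markers <= 400  # 4/5 of markers, minus monomorphic
        assert grm.n_markers > 350
        assert grm.excluded_chrom == "chr2"

    def test_unknown_chromosome_rejected(self):
        pseudo = _pseudo_from_dosages(np.random.default_rng(4).binomial(2, 0.5, (10, 50)), 2)
        with pytest.raises(ValueError):
            loco_grm(pseudo, "chr99")

    def test_single_chromosome_rejected(self):
        pseudo = _pseudo_from_dosages(np.random.default_rng(5).binomial(2, 0.5, (10, 50)), 1)
        with pytest.raises(ValueError):
            loco_grm(pseudo, "chr1")

    def test_loco_approaches_full_grm_with_many_chromosomes(self):
        rng = np.random.default_rng(6)
        dosages = rng.binomial(2, 0.5, size=(40, 2000))
        pseudo = _pseudo_from_dosages(dosages, n_chrom=20)
        full = compute_grm(pseudo)
        part = loco_grm(pseudo, "chr7")
        assert np.max(np.abs(full.matrix - part.matrix)) < 0.1


class TestFitNullLmm:
    def _grm_and_pseudo(self, n, m, seed):
        rng = np.random.default_rng(seed)
        pseudo = _pseudo_from_dosages(rng.binomial(2, 0.5, size=(n, m)))
        return compute_grm(pseudo), pseudo

    def test_no_genetic_variance_estimated_near_zero(self):
        grm, _ = self._grm_and_pseudo(500, 2000, 7)
        y = np.random.default_rng(8).normal(size=500)
        fit = fit_null_lmm(y, grm)
        assert fit.heritability < 0.05

    def test_recovers_moderate_heritability(self):
        grm, _ = self._grm_and_pseudo(500, 2000, 9)
        rng = np.random.default_rng(10)
        S, U = grm.eig()
        g = U @ (np.sqrt(np.maximum(S, 0)) * rng.normal(size=500))
        g *= np.sqrt(0.5) / g.std()
        y = g + rng.normal(0, np.sqrt(0.5), size=500)
        fit = fit_null_lmm(y, grm)
        assert abs(fit.heritability - 0.5) < 0.15

    def test_optimum_beats_random_variance_ratios(self):
        grm, _ = self._grm_and_pseudo(100, 500, 11)
        rng = np.random.default_rng(12)
        y = rng.normal(size=100) + 0.5 * grm.matrix @ rng.normal(size=100)
        fit = fit_null_lmm(y, grm)
        from crossqtl.association import _reml_neg_loglik

        S, U = grm.eig()
        yt, Wt = U.T @ y, U.T @ np.ones((100, 1))
        for log_ratio in rng.uniform(-8, 8, size=20):
            assert fit.log_likelihood >= -_reml_neg_loglik(log_ratio, yt, Wt, S) - 1e-6

    def test_mismatched_dimensions_rejected(self):
        grm, _ = self._grm_and_pseudo(20, 100, 13)
        with pytest.raises(ValueError):
            fit_null_lmm(np.zeros(19), grm)


class TestAssociationScan:
    def test_identity_grm_reduces_to_ols(self):
        """With G = I the covariance is white for any variance ratio, so
        every p-value must equal the OLS z-based p-value."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(14)
        n, m = 120, 60
        pseudo = _pseudo_from_dosages(rng.binomial(2, 0.5, (n, m)), n_chrom=2)
        y = rng.normal(size=n) + 0.4 * pseudo.dosages[:, 5]
        eye = {c: GRM(matrix=np.eye(n), n_markers=1) for c in ("chr1", "chr2")}
        scan = association_scan(y, pseudo, eye)
        for j in [0, 5, 17, 59]:
            X = sm.add_constant(pseudo.dosages[:, j].astype(float))
            res = sm.OLS(y, X).fit(use_t=False)
            assert scan["p"].iloc[j] == pytest.approx(res.pvalues[1], rel=1e-8)
            assert scan["beta"].iloc[j] == pytest.approx(res.params[1], rel=1e-8)

    def test_qtl_recovered_without_polygenic_background(self):
        layout = GenomeLayout(tuple((f"chr{i+1}", 5_000_000) for i in range(5)), 5000)
        beta = effect_for_pve(0.2, background_var=1.0)
        cfg = CrossSimConfig(
            layout=layout, n_f2=600, seed=15,
            qtl_spec=[("chr3", 500, beta)], residual_var=1.0,
        )
        truth, counts = simulate_f2_cohort(cfg)
        from crossqtl import bin_allele_counts, decode_genotypes, fill_missing

        freqs = bin_allele_counts(counts, counts.panel, layout)
        pseudo = build_pseudosnps(fill_missing(decode_genotypes(freqs)))
        y = simulate_phenotypes(truth, cfg)["value"].to_numpy()
        scan = association_scan(y, pseudo)
        peak = scan.loc[scan["p"].idxmin()]
        assert peak["chrom"] == "chr3"
        assert abs(peak["start"] + 2500 - 2_502_500) <= 250_000

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(16)
        n, m = 500, 5000
        pseudo = _pseudo_from_dosages(rng.binomial(2, 0.5, (n, m)), n_chrom=5)
        y = rng.normal(size=n)
        chroms = [f"chr{i+1}" for i in range(5)]
        grms = {c: loco_grm(pseudo, c) for c in chroms}
        scan = association_scan(y, pseudo, grms)
        from scipy.stats import kstest

        ks = kstest(scan["p"], "uniform").statistic
        assert ks < 0.05

    def test_monomorphic_marker_gets_p_one_not_error(self):
        rng = np.random.default_rng(17)
        dosages = rng.binomial(2, 0.5, (50, 20))
        dosages[:, 3] = 1
        pseudo = _pseudo_from_dosages(dosages, n_chrom=2)
        y = rng.normal(size=50)
        eye = {c: GRM(matrix=np.eye(50), n_markers=1) for c in ("chr1", "chr2")}
        scan = association_scan(y, pseudo, eye)
        assert scan["p"].iloc[3] == 1.0
        assert scan["monomorphic"].iloc[3]

    def test_exchangeability_under_joint_sample_reordering(self):
        rng = np.random.default_rng(18)
        n = 80
        pseudo = _pseudo_from_dosages(rng.binomial(2, 0.5, (n, 100)), n_chrom=2)
        covar = rng.normal(size=(n, 1))
        y = rng.normal(size=n) + 0.5 * covar[:, 0]
        grms = {c: loco_grm(pseudo, c) for c in ("chr1", "chr2")}
        scan1 = association_scan(y, pseudo, grms, covar)

        perm = rng.permutation(n)
        pseudo2 = _pseudo_from_dosages(pseudo.dosages[perm], n_chrom=2)
        grms2 = {c: loco_grm(pseudo2, c) for c in ("chr1", "chr2")}
        scan2 = association_scan(y[perm], pseudo2, grms2, covar[perm])
        np.testing.assert_allclose(scan1["p"], scan2["p"], rtol=1e-8, atol=1e-12)


class TestPermutationThreshold:
    def _setup(self, seed=19, n=60, m=80):
        rng = np.random.default_rng(seed)
        pseudo = _pseudo_from_dosages(rng.binomial(2, 0.5, (n, m)), n_chrom=2)
        y = rng.normal(size=n)
        grms = {c: loco_grm(pseudo, c) for c in ("chr1", "chr2")}
        return y, pseudo, grms

    def test_threshold_is_min_of_reported_minima(self):
        y, pseudo, grms = self._setup()
        thr, minima = permutation_threshold(y, pseudo, grms, n_perm=5, seeds=[1, 2, 3, 4, 5])
        assert thr == min(minima)
        assert len(minima) == 5

    def test_identical_seed_list_reproduces_threshold(self):
        y, pseudo, grms = self._setup()
        t1, _ = permutation_threshold(y, pseudo, grms, n_perm=3, seeds=[7, 8, 9])
        t2, _ = permutation_threshold(y, pseudo, grms, n_perm=3, seeds=[7, 8, 9])
        assert t1 == t2

    def test_more_permutations_never_raise_threshold(self):
        # min over a superset of permutations cannot exceed min over a subset
        y, pseudo, grms = self._setup()
        seeds = list(range(10))
        t1, _ = permutation_threshold(y, pseudo, grms, n_perm=1, seeds=seeds[:1])
        t10, _ = permutation_threshold(y, pseudo, grms, n_perm=10, seeds=seeds)
        assert t10 <= t1

    def test_zero_permutations_rejected(self):
        y, pseudo, grms = self._setup()
        with pytest.raises(ValueError):
            permutation_threshold(y, pseudo, grms, n_perm=0, seeds=[])


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,alpha,expected", [(1000, 0.05, 5e-5), (1, 0.05, 0.05), (100, 0.01, 1e-4)]
    )
    def test_threshold_arithmetic(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected, rel=1e-12)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestCallSignificant:
    def _scan(self, pvals, starts=None):
        m = len(pvals)
        starts = np.arange(m) * 5000 if starts is None else np.asarray(starts)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 5000,
                "bin_id": [f"chr1:{s}-{s+5000}" for s in starts],
                "p": pvals,
            }
        )

    def test_no_significant_markers_gives_empty_loci(self):
        loci = call_significant(self._scan([1.0, 1.0, 1.0]), 0.01, 0.001)
        assert len(loci) == 0

    def test_single_bin_locus_flagged_for_both_thresholds(self):
        loci = call_significant(self._scan([1.0, 1e-6, 1.0]), 0.01, 1e-4)
        assert len(loci) == 1
        assert loci.iloc[0]["sig_perm"] and loci.iloc[0]["sig_bonf"]
        assert loci.iloc[0]["peak_start"] == 5000

    def test_adjacent_significant_bins_merge_into_one_locus(self):
        loci = call_significant(self._scan([1e-5, 1e-6, 1.0, 1e-5]), 1e-3)
        assert len(loci) == 2
        assert loci.iloc[0]["n_bins"] == 2
        assert loci.iloc[0]["peak_start"] == 5000
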