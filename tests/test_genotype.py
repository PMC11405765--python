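import numpy as np
import pytest

from crossqtl import (
    CrossSimConfig,
    GenomeLayout,
    HMMSpec,
    bin_allele_counts,
    build_pseudosnps,
    count_state_changes,
    decode_genotypes,
    fill_missing,
    qc_samples,
    simulate_f2_cohort,
)
from crossqtl.genome import SNPPanel
from crossqtl.genotype import BinFrequencies, GenotypeCalls, _viterbi_batch
from crossqtl.simulate import AlleleCounts

from conftest import brute_force_viterbi


def _freqs_from_values(values, layout=None, snp_count=None):
    """Single-sample BinFrequencies on a one-chromosome layout."""
    values = np.asarray(values, dtype=float)
    if layout is None:
        layout = GenomeLayout((("chr1", 5000 * values.size),), bin_size=5000)
    if snp_count is None:
        snp_count = np.ones(values.size, dtype=np.int64)
    return BinFrequencies(
        layout=layout,
        sample_ids=["s0"],
        freq=values[None, :],
        reads=np.ones((1, values.size), dtype=np.int64),
        snp_count=np.asarray(snp_count),
    )


class TestBinAlleleCounts:
    def _one_bin_counts(self, cab, kaga):
        layout = GenomeLayout((("chr1", 10_000),), bin_size=5000)
        pos = np.arange(len(cab), dtype=np.int64) * 100
        panel = SNPPanel(layout, {"chr1": pos})
        return (
            AlleleCounts(
                panel,
                {"chr1": np.asarray([cab], dtype=np.uint16)},
                {"chr1": np.asarray([kaga], dtype=np.uint16)},
                ["s0"],
            ),
            panel,
            layout,
        )

    @pytest.mark.parametrize(
        "cab,kaga,expected",
        [
            ([3, 0], [1, 0], 0.25),
            ([0, 0], [0, 0], 0.5),  # zero-read bin pinned at 0.5
            ([0, 0], [3, 4], 1.0),
        ],
    )
    def test_bin_frequency_arithmetic(self, cab, kaga, expected):
        counts, panel, layout = self._one_bin_counts(cab, kaga)
        freqs = bin_allele_counts(counts, panel, layout)
        assert freqs.freq[0, 0] == pytest.approx(expected)

    def test_second_bin_without_snps_flagged_missing(self):
        counts, panel, layout = self._one_bin_counts([1], [1])
        freqs = bin_allele_counts(counts, panel, layout)
        assert list(freqs.missing_bins) == [False, True]
        assert freqs.freq[0, 1] == 0.5

    def test_sums_multiple_sites_within_bin(self):
        counts, panel, layout = self._one_bin_counts([2, 1], [1, 4])
        freqs = bin_allele_counts(counts, panel, layout)
        assert freqs.freq[0, 0] == pytest.approx(5 / 8)
        assert freqs.reads[0, 0] == 8


class TestDecodeGenotypes:
    def test_constant_low_frequency_decodes_homozygous_cab(self):
        calls = decode_genotypes(_freqs_from_values(np.zeros(100)))
        assert np.all(calls.states == 0)

    def test_constant_high_frequency_decodes_homozygous_kaga(self):
        calls = decode_genotypes(_freqs_from_values(np.ones(100)))
        assert np.all(calls.states == 2)

    def test_step_sequence_matches_exhaustive_enumeration(self):
        # With near-zero transitions a switch costs ~log(1e-8), so over six
        # bins the enumeration optimum is the transition-free het path; the
        # decoder must reproduce whatever enumeration says is optimal.
        obs = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        spec = HMMSpec()
        expected = brute_force_viterbi(obs, spec)
        calls = decode_genotypes(_freqs_from_values(obs), spec)
        np.testing.assert_array_equal(calls.states[0], expected)

    def test_long_step_sequence_decodes_two_blocks(self):
        # at block lengths long enough to amortise the transition penalty
        # the decoder recovers the hom-Cab -> hom-Kaga structure exactly
        obs = np.r_[np.zeros(150), np.ones(150)]
        calls = decode_genotypes(_freqs_from_values(obs))
        np.testing.assert_array_equal(calls.states[0], np.r_[np.zeros(150), np.full(150, 2)])

    def test_all_missing_chromosome_rejected(self):
        freqs = _freqs_from_values(np.full(4, 0.5), snp_count=np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            decode_genotypes(freqs)

    def test_matches_hmmlearn_reference_decoder(self):
        # the reference tool for this decoding task; same fixed parameters
        hmm = pytest.importorskip("hmmlearn.hmm")
        spec = HMMSpec()
        model = hmm.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        model.startprob_ = np.asarray(spec.start_prob)
        model.transmat_ = spec.transmat
        model.means_ = np.asarray(spec.means)[:, None]
        model.covars_ = np.full((3, 1), spec.emission_var)
        rng = np.random.default_rng(0)
        for _ in range(10):
            obs = rng.uniform(0, 1, size=300)
            _, ref_path = model.decode(obs[:, None], algorithm="viterbi")
            ours = _viterbi_batch(obs[None, :], spec)[0]
            np.testing.assert_array_equal(ours, ref_path)

    def test_allele_relabeling_symmetry(self):
        # f -> 1-f must swap states 0<->2, keep 1, and preserve change counts
        rng = np.random.default_rng(1)
        obs = rng.uniform(0, 1, size=(5, 200))
        spec = HMMSpec()
        a = _viterbi_batch(obs, spec)
        b = _viterbi_batch(1.0 - obs, spec)
        np.testing.assert_array_equal(2 - a, b)


class TestFillMissing:
    def _calls(self, states, missing):
        states = np.asarray(states, dtype=np.int8)[None, :]
        layout = GenomeLayout((("chr1", 5000 * states.shape[1]),), bin_size=5000)
        return GenotypeCalls(layout, ["s0"], states, np.asarray(missing, dtype=bool))

    @pytest.mark.parametrize(
        "states,missing,expected",
        [
            ([-1, 0, -1, 2], [1, 0, 1, 0], [0, 0, 0, 2]),
            ([0, 1, 2, 1], [0, 0, 0, 0], [0, 1, 2, 1]),  # no-op without gaps
            ([-1, -1, 1], [1, 1, 0], [1, 1, 1]),  # leading gap takes next call
        ],
    )
    def test_filling_rule(self, states, missing, expected):
        filled = fill_missing(self._calls(states, missing))
        assert list(filled.states[0]) == expected
        assert list(filled.filled) == [bool(m) for m in missing]

    def test_fully_missing_chromosome_rejected(self):
        with pytest.raises(ValueError):
            fill_missing(self._calls([-1, -1], [1, 1]))


class TestQcSamples:
    def _cohort(self, reads):
        reads = np.asarray(reads)
        layout = GenomeLayout((("chr1", 5000 * reads.shape[1]),), bin_size=5000)
        return BinFrequencies(
            layout=layout,
            sample_ids=[f"s{i}" for i in range(reads.shape[0])],
            freq=np.full(reads.shape, 0.5),
            reads=reads,
            snp_count=np.ones(reads.shape[1], dtype=np.int64),
        )

    def test_zero_coverage_sample_excluded(self):
        freqs = self._cohort([[1, 1, 1, 1], [0, 0, 0, 0]])
        kept, excluded, frac = qc_samples(freqs, 0.5)
        assert kept == ["s0"] and excluded == ["s1"]
        np.testing.assert_allclose(frac, [1.0, 0.0])

    def test_zero_threshold_keeps_everything(self):
        freqs = self._cohort([[0, 0, 0, 0]])
        kept, excluded, _ = qc_samples(freqs, 0.0)
        assert kept == ["s0"] and excluded == []

    def test_depth_separates_deep_from_shallow_samples(self):
        layout = GenomeLayout((("chr1", 500_000),), bin_size=5000)
        deep = simulate_f2_cohort(CrossSimConfig(layout=layout, n_f2=5, seed=1, depth_mean=1.0))[1]
        shallow = simulate_f2_cohort(
            CrossSimConfig(layout=layout, n_f2=5, seed=1, depth_mean=0.01)
        )[1]
        for counts, expect_kept in ((deep, True), (shallow, False)):
            freqs = bin_allele_counts(counts, counts.panel, layout)
            kept, excluded, _ = qc_samples(freqs, 0.5)
            assert (len(excluded) == 0) is expect_kept

    def test_empty_cohort_rejected(self):
        freqs = self._cohort([[1]])
        freqs.sample_ids = []
        with pytest.raises(ValueError):
            qc_samples(freqs)


class TestPseudoSNPs:
    def _calls(self, states):
        states = np.asarray(states, dtype=np.int8)
        layout = GenomeLayout((("chr1", 5000 * states.shape[1]),), bin_size=5000)
        return GenotypeCalls(
            layout,
            [f"s{i}" for i in range(states.shape[0])],
            states,
            np.zeros(states.shape[1], dtype=bool),
        )

    def test_dosage_equals_state_code(self):
        mat = build_pseudosnps(self._calls([[0, 1, 2]]))
        np.testing.assert_array_equal(mat.dosages, [[0, 1, 2]])
        assert mat.bin_ids == ["chr1:0-5000", "chr1:5000-10000", "chr1:10000-15000"]

    def test_constant_column_flagged_monomorphic(self):
        mat = build_pseudosnps(self._calls([[1, 0], [1, 2]]))
        assert list(mat.monomorphic) == [True, False]

    def test_unfilled_calls_rejected(self):
        calls = self._calls([[0, 1, 2]])
        calls.states[0, 1] = -1
        with pytest.raises(ValueError):
            build_pseudosnps(calls)

    def test_cohort_mean_dosage_is_mendelian(self, desk_pseudosnps):
        # dosage expectation under 0.25/0.5/0.25 segregation is exactly 1
        col_means = desk_pseudosnps.dosages.mean(axis=0)
        assert abs(col_means.mean() - 1.0) < 0.05


class TestCountStateChanges:
    @pytest.mark.parametrize(
        "states,expected",
        [([0, 0, 0, 0], 0), ([0, 0, 1, 1], 1), ([0, 1, 0, 1], 3)],
    )
    def test_change_counting(self, states, expected):
        states = np.asarray(states, dtype=np.int8)[None, :]
        layout = GenomeLayout((("chr1", 5000 * states.shape[1]),), bin_size=5000)
        calls = GenotypeCalls(layout, ["s0"], states, np.zeros(states.shape[1], dtype=bool))
        assert count_state_changes(calls)[0, 0] == expected


class TestGenotypingAccuracy:
    def test_desk_scale_accuracy_and_parsimony(self, desk_cohort, desk_calls):
        """At ~1x depth with near-zero transitions, >=95% of bins get their
        true state, and the decoded path never invents many more blocks
        than the true crossovers allow."""
        cfg, truth, _ = desk_cohort
        _, _, _, calls = desk_calls
        accuracy = (calls.states == truth.states).mean()
        assert accuracy >= 0.95

        changes = count_state_changes(calls)
        for i, (g1, g2) in enumerate(truth.gametes):
            for j, chrom in enumerate(cfg.layout.names):
                true_co = g1.crossovers[chrom].size + g2.crossovers[chrom].size
                assert changes[i, j] <= true_co + 2
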