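import numpy as np
import pytest

from crossqtl import (
    CrossSimConfig,
    GenomeLayout,
    bin_allele_counts,
    build_pseudosnps,
    decode_genotypes,
    fill_missing,
    simulate_f2_cohort,
)

#: seed for every session-scoped simulation fixture
COHORT_SEED = 11


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 800_000)), bin_size=5000)


@pytest.fixture(scope="session")
def desk_cohort():
    """Default desk-scale cohort: 5 chr x 5 Mb, 150 F2s at ~1x depth.

    Shared by the genotyping-accuracy, parsimony and Mendelian-ratio
    checks so the expensive simulation runs once.
    """
    cfg = CrossSimConfig(n_f2=150, seed=COHORT_SEED)
    truth, counts = simulate_f2_cohort(cfg)
    return cfg, truth, counts


@pytest.fixture(scope="session")
def desk_calls(desk_cohort):
    cfg, truth, counts = desk_cohort
    freqs = bin_allele_counts(counts, counts.panel, cfg.layout)
    calls = fill_missing(decode_genotypes(freqs))
    return cfg, truth, freqs, calls


@pytest.fixture(scope="session")
def desk_pseudosnps(desk_calls):
    _, _, _, calls = desk_calls
    return build_pseudosnps(calls)


def brute_force_viterbi(obs, spec):
    """Exhaustive most-probable-path search over all 3^T state sequences.

    Independent oracle for the dynamic-programming decoder; only feasible
    for short sequences.
    """
    obs = np.asarray(obs, dtype=float)
    T = obs.size
    paths = np.indices((3,) * T).reshape(T, -1).T  # (3^T, T)
    means = np.asarray(spec.means)
    ll = -0.5 * (obs[None, :] - means[paths]) ** 2 / spec.emission_var
    ll = ll.sum(axis=1)
    ll += np.log(np.asarray(spec.start_prob))[paths[:, 0]]
    log_trans = np.log(spec.transmat)
    ll += log_trans[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths[np.argmax(ll)]
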