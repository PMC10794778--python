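import numpy as np
import pytest

from methylandscape import simulate as sim


@pytest.fixture(scope="session")
def small_seq_truth():
    """A small genome WITH explicit sequence (2 chromosomes x 2 Mb)."""
    config = sim.SimulationConfig(
        seed=11, n_chromosomes=2, chrom_length=2_000_000, bin_width=100_000,
        emit_sequence=True,
    )
    return sim.simulate_genome(config)


@pytest.fixture(scope="session")
def desk_truth():
    """Desk-scale sequence-free genome: 4 chromosomes x 60 Mb, 480 bins of
    500 kb, ~2.4M CpGs at realistic density."""
    return sim.simulate_genome(sim.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def landscape_truth():
    """4,800-bin landscape (the mouse autosomal usable-bin count) at reduced
    CpG density."""
    return sim.simulate_genome(sim.landscape_4800(seed=13))


def brute_force_rank_sum_p(x, y):
    """Exhaustive-permutation two-sided p for the rank-sum test (tie-free).

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments at least as extreme (in Mann-Whitney U, folded about
    its symmetric centre) as observed.
    """
    from itertools import combinations

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    order = pooled.argsort()
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    centre = n1 * (n - n1) / 2
    extreme = 0
    total = 0
    for comb in combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        extreme += abs(u - centre) >= abs(u_obs - centre) - 1e-9
        total += 1
    return extreme / total
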