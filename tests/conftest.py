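"""Shared fixtures: small random matrices, a community-scale calibration
fixture, and brute-force oracles kept deliberately independent of the
package's fast code paths."""

from itertools import permutations

import numpy as np
import pytest
from skbio.stats.distance import DistanceMatrix

from betagwas import (
    NullMomentCalculator,
    SimulationDesign,
    center_distances,
    interaction_null_residuals,
    permutation_oracle,
    simulate_distance_matrix,
    simulate_environment,
)


def random_distance_matrix(n, rng, scale=1.0):
    """Generic symmetric nonnegative matrix with zero diagonal."""
    d = np.abs(rng.normal(scale, 0.4 * scale, (n, n)))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"S{i + 1}" for i in range(n)])


def brute_force_distinct_sum(A, edges):
    """Sum of prod A[i_u, i_v] over injective vertex assignments, by loops."""
    k = 1 + max(max(e) for e in edges)
    n = A.shape[0]
    total = 0.0
    for tup in permutations(range(n), k):
        p = 1.0
        for u, v in edges:
            p *= A[tup[u], tup[v]]
        total += p
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cd():
    """Centered 6-subject matrix used by the enumeration-oracle tests."""
    r = np.random.default_rng(11)
    return center_distances(random_distance_matrix(6, r))


@pytest.fixture(scope="session")
def community_matrix_100():
    """One fixed Bray-Curtis matrix of 100 synthetic communities (null)."""
    dm, _ = simulate_distance_matrix(SimulationDesign(n=100, seed=1))
    return dm


@pytest.fixture(scope="session")
def calibration_run(community_matrix_100):
    """Null-replicate scores and exact moments on the fixed 100-subject study.

    120,000 iid HWE genotype redraws at MAF 20% with a binary environment at
    50% frequency, shared across the calibration-oriented tests.
    """
    dm = community_matrix_100
    f = 0.2
    env = simulate_environment(100, np.random.default_rng(7))
    cd_main = center_distances(dm)
    cd_int = interaction_null_residuals(dm, env)
    nm_main = NullMomentCalculator(cd_main).at(f)
    nm_int = NullMomentCalculator(cd_int, env).at(f)
    reps = 120_000
    orc_main = permutation_oracle(cd_main, f, reps=reps, rng=101, batch=40_000)
    orc_int = permutation_oracle(cd_int, f, env=env, reps=reps, rng=102,
                                 batch=40_000)
    return {
        "f": f,
        "env": env,
        "reps": reps,
        "cd_main": cd_main,
        "cd_int": cd_int,
        "nm_main": nm_main,
        "nm_int": nm_int,
        "orc_main": orc_main,
        "orc_int": orc_int,
    }
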