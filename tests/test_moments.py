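"""Analytic null moments vs exact enumeration and Monte-Carlo oracles."""

import numpy as np
import pytest
from skbio.stats.distance import DistanceMatrix

from betagwas import (
    NullMomentCalculator,
    SimulationDesign,
    center_distances,
    delta_moments,
    exact_enumeration_oracle,
    genotype_pair_moments,
    interaction_null_residuals,
    permutation_oracle,
    replicate_subjects,
    score_skew_kurt,
    score_variance,
    scores_correlation,
    simulate_distance_matrix,
    simulate_environment,
)
from betagwas.moments import MomentEngine
from betagwas.patterns import KIND_INTER, KIND_MAIN

from conftest import brute_force_distinct_sum, random_distance_matrix


class TestPairMoments:
    def test_worked_values_at_half(self):
        gm = genotype_pair_moments(0.5)
        assert gm.hwe == pytest.approx((0.25, 0.5, 0.25))
        assert gm.mean_G == pytest.approx(0.75)
        assert gm.var_G == pytest.approx(0.4375)
        assert gm.cov_G == pytest.approx(0.0625)

    def test_moments_vanish_monotonically_toward_zero_maf(self):
        fs = [0.02, 0.01, 0.005, 0.002]
        vars_ = [genotype_pair_moments(f).var_G for f in fs]
        assert all(a > b > 0 for a, b in zip(vars_, vars_[1:]))

    @pytest.mark.parametrize("f", [0.0, 0.6, -0.1])
    def test_maf_domain_enforced(self, f):
        with pytest.raises(ValueError):
            genotype_pair_moments(f)

    def test_delta_reduces_to_genetic_distance_when_env_is_one(self):
        gm = genotype_pair_moments(0.3)
        dmom = delta_moments(0.3, np.ones(10))
        assert dmom.var_delta == pytest.approx(gm.var_G, rel=1e-12)
        assert dmom.cov_delta == pytest.approx(gm.cov_G, rel=1e-12)
        assert dmom.cov_g_delta_same == pytest.approx(gm.var_G, rel=1e-12)

    def test_delta_vanishes_when_env_is_zero(self):
        dmom = delta_moments(0.3, np.zeros(10))
        assert dmom.var_delta == 0.0 and dmom.cov_delta == 0.0


class TestEnumerationOracle:
    """Analytic Var/gamma/kappa/rho equal exact 3^N HWE enumeration."""

    @pytest.mark.parametrize("f", [0.1, 0.2, 0.3, 0.5])
    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_main_effect_moments_are_exact(self, n, f):
        r = np.random.default_rng(n)
        cd = center_distances(random_distance_matrix(n, r))
        nm = NullMomentCalculator(cd).at(f)
        orc = exact_enumeration_oracle(cd, f)["main"]
        assert nm.var_M == pytest.approx(orc["var"], rel=1e-9)
        assert nm.gamma_M == pytest.approx(orc["gamma"], rel=1e-9)
        assert nm.kappa_M == pytest.approx(orc["kappa"], rel=1e-9)

    @pytest.mark.parametrize("f", [0.2, 0.5])
    @pytest.mark.parametrize("n", [6, 7])
    def test_interaction_and_mixed_moments_are_exact(self, n, f):
        r = np.random.default_rng(100 + n)
        cd = center_distances(random_distance_matrix(n, r))
        env = (r.random(n) < 0.5).astype(float)
        if np.ptp(env) == 0:  # force both strata present
            env[0] = 1.0 - env[0]
        nm = NullMomentCalculator(cd, env).at(f)
        orc = exact_enumeration_oracle(cd, f, env)
        assert nm.mean_I == pytest.approx(orc["interaction"]["mean"], rel=1e-9)
        assert nm.var_I == pytest.approx(orc["interaction"]["var"], rel=1e-9)
        assert nm.gamma_I == pytest.approx(orc["interaction"]["gamma"], rel=1e-9)
        assert nm.kappa_I == pytest.approx(orc["interaction"]["kappa"], rel=1e-9)
        assert nm.rho == pytest.approx(orc["rho"], rel=1e-9)
        sm, si = np.sqrt(nm.var_M), np.sqrt(nm.var_I)
        for (a, b), want in orc["mixed"].items():
            if a + b < 3 or (a, b) not in nm.std_mixed:
                continue
            got = nm.std_mixed[(a, b)] * sm**a * si**b
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_closed_form_variance_agrees_with_engine(self, small_cd):
        for f in (0.1, 0.3, 0.5):
            gm = genotype_pair_moments(f)
            closed = score_variance(small_cd, gm)
            engine = NullMomentCalculator(small_cd).at(f).var_M
            assert closed == pytest.approx(engine, rel=1e-12)

    def test_three_level_environment_moments_are_exact(self):
        r = np.random.default_rng(42)
        cd = center_distances(random_distance_matrix(6, r))
        env = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        nm = NullMomentCalculator(cd, env).at(0.25)
        orc = exact_enumeration_oracle(cd, 0.25, env)
        assert nm.var_I == pytest.approx(orc["interaction"]["var"], rel=1e-9)
        assert nm.gamma_I == pytest.approx(orc["interaction"]["gamma"], rel=1e-9)


class TestMonteCarloAgreement:
    def test_analytic_moments_match_genotype_redraws(self, calibration_run):
        """At N=100 the analytic moments sit inside the Monte-Carlo bands."""
        cal = calibration_run
        nm, orc = cal["nm_main"], cal["orc_main"]["main"]
        reps = cal["reps"]
        assert orc["var"] / nm.var_M == pytest.approx(1.0, abs=4 * np.sqrt(2 / reps) * 3)
        assert orc["gamma"] == pytest.approx(nm.gamma_M, abs=0.03)
        assert orc["kappa"] == pytest.approx(nm.kappa_M, abs=0.12)
        nmi, orci = cal["nm_int"], cal["orc_int"]
        assert orci["interaction"]["var"] / nmi.var_I == pytest.approx(1.0, abs=0.05)
        assert orci["interaction"]["mean"] == pytest.approx(
            nmi.mean_I, abs=4 * np.sqrt(nmi.var_I / reps)
        )
        assert orci["rho"] == pytest.approx(nmi.rho, abs=0.02)


class TestStructuralProperties:
    def test_skew_kurt_invariant_to_distance_rescaling(self, small_cd):
        g1, k1 = score_skew_kurt(small_cd, 0.2)
        scaled = center_distances(small_cd.dprime * 37.5)
        g2, k2 = score_skew_kurt(scaled, 0.2)
        assert g2 == pytest.approx(g1, rel=1e-9)
        assert k2 == pytest.approx(k1, rel=1e-9)

    def test_grid_interpolation_error_is_small(self, community_matrix_100):
        calc = NullMomentCalculator(center_distances(community_matrix_100))
        grid = calc.grid()
        for f in (0.1025, 0.2175, 0.3925):  # off-grid points
            exact = calc.at(f)
            interp = grid.at(f)
            assert interp.gamma_M == pytest.approx(exact.gamma_M, rel=1e-3)
            assert interp.var_M == pytest.approx(exact.var_M, rel=1e-3)

    def test_moments_continuous_in_maf(self, small_cd):
        # skewness/kurtosis diverge as f -> 0 (no minor alleles), so the
        # smoothness budget applies on the working MAF range
        fs = np.linspace(0.05, 0.5, 50)
        g, k = score_skew_kurt(small_cd, fs)
        assert np.all(np.isfinite(g)) and np.all(np.isfinite(k))
        # no jumps: successive differences bounded by a smoothness budget
        assert np.max(np.abs(np.diff(g))) < 0.15
        assert np.max(np.abs(np.diff(k))) < 0.8

    def test_rho_is_one_when_env_constant_one(self):
        r = np.random.default_rng(9)
        cd = center_distances(random_distance_matrix(6, r))
        assert scores_correlation(cd, 0.3, np.ones(6)) == pytest.approx(1.0)

    def test_scaling_laws_on_replicated_family(self):
        """gamma ~ N^-1/2 and kappa ~ 1/N on a structure-preserving family."""
        dm, _ = simulate_distance_matrix(SimulationDesign(n=120, seed=1))
        gk = {}
        for k in (1, 2):
            cd = center_distances(replicate_subjects(dm, k) if k > 1 else dm)
            nm = NullMomentCalculator(cd).at(0.25)
            gk[k] = (nm.gamma_M, nm.kappa_M)
        assert gk[2][0] / gk[1][0] == pytest.approx(2 ** -0.5, rel=0.10)
        assert gk[2][1] / gk[1][1] == pytest.approx(0.5, rel=0.10)

    def test_skewness_smaller_at_maf_half_than_quarter(self, community_matrix_100):
        cd = center_distances(community_matrix_100)
        g25, k25 = score_skew_kurt(cd, 0.25)
        g50, k50 = score_skew_kurt(cd, 0.5)
        assert g50 < g25 and k50 < k25


class TestTypedDistinctSums:
    def test_stratified_sums_match_brute_force(self):
        r = np.random.default_rng(17)
        cd = center_distances(random_distance_matrix(7, r))
        env = np.array([0, 1, 0, 1, 1, 0, 1], float)
        eng = MomentEngine(cd.dprime, env)
        # brute force with stratum indicator weights folded into the loop
        from itertools import permutations, product

        for edges in [((0, 1), (0, 2)), ((0, 1), (1, 2), (0, 2)),
                      ((0, 1), (0, 1), (1, 2))]:
            k = 1 + max(max(e) for e in edges)
            for tau in product(range(2), repeat=k):
                fast = eng._ds.dsum(edges, tau)
                brute = 0.0
                for tup in permutations(range(7), k):
                    if any(int(env[tup[v]]) != tau[v] for v in range(k)):
                        continue
                    p = 1.0
                    for u, v in edges:
                        p *= cd.dprime[tup[u], tup[v]]
                    brute += p
                np.testing.assert_allclose(fast, brute, rtol=1e-10, atol=1e-12)
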