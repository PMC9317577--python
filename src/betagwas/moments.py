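"""Exact null moments of distance-association scores under Hardy-Weinberg genotypes.

The null model conditions on the (residualized) distance matrix and on the
observed environment vector, and randomizes genotypes only: each subject's
dosage is an iid draw from {0, 1, 2} with Hardy-Weinberg probabilities
``((1-f)^2, 2f(1-f), f^2)`` at minor-allele frequency ``f``.  Under this
null the variance, skewness and kurtosis of the main-effect score ``S_M``
and the interaction score ``S_I`` (and all their cross-moments) factor into
distance-structure sums -- fixed per study -- times genotype moments that
depend only on ``f`` and the environment strata, which is what makes a
MAF-grid precomputation possible for a genome-wide scan.

Everything here is assembled by the programmatic pattern engine in
:mod:`betagwas.patterns`; no moment formula is hand-derived.  The test suite
certifies the assembly against exact enumeration over all ``3^N`` genotype
vectors on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product as iter_product
from math import comb

import numpy as np

from .patterns import KIND_INTER, KIND_MAIN, DistinctSums, edge_patterns

__all__ = [
    "hwe_probs",
    "GenotypeMoments",
    "DeltaMoments",
    "NullMoments",
    "genotype_pair_moments",
    "delta_moments",
    "score_variance",
    "score_skew_kurt",
    "scores_correlation",
    "MomentEngine",
    "NullMomentCalculator",
    "NullMomentGrid",
]

#: default MAF grid used by genome-wide scans
DEFAULT_GRID = np.round(np.arange(0.005, 0.5000001, 0.005), 6)

#: moment orders (a, b) of E[S_M^a S_I^b] kept for the joint test corrections
MIXED_ORDERS = [
    (2, 0), (0, 2), (1, 1),
    (3, 0), (2, 1), (1, 2), (0, 3),
    (4, 0), (3, 1), (2, 2), (1, 3), (0, 4),
]


def hwe_probs(f):
    """Hardy-Weinberg genotype probabilities ((1-f)^2, 2f(1-f), f^2).

    ``f`` may be a scalar or an array; returns shape ``(..., 3)``.
    """
    f = np.asarray(f, dtype=float)
    return np.stack([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2], axis=-1)


def _check_maf(f):
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or np.any(f > 0.5):
        raise ValueError("minor-allele frequency must lie in (0, 0.5]")
    return f


@lru_cache(maxsize=None)
def _genotype_tuples(k: int) -> np.ndarray:
    """All genotype assignments {0,1,2}^k as an int array of shape (3^k, k)."""
    grid = np.indices((3,) * k).reshape(k, -1).T
    return np.ascontiguousarray(grid)


def pair_mean(e_u: float, e_v: float, f) -> np.ndarray:
    """E |g_u e_u - g_v e_v| over two independent HWE genotypes; shape (F,)."""
    P = hwe_probs(np.atleast_1d(f))
    a = np.arange(3, dtype=float)
    vals = np.abs(a[:, None] * e_u - a[None, :] * e_v)
    return np.einsum("fa,fb,ab->f", P, P, vals)


def pattern_moment(edges, levels, f) -> np.ndarray:
    """E[prod over edges of centered kernel] for one pattern at env ``levels``.

    ``edges`` are ``(kind, u, v)`` triples; ``levels`` gives the environment
    value of each pattern vertex; ``f`` is a MAF scalar or grid.  The
    expectation is over iid HWE genotypes on the pattern's vertices,
    evaluated by exact enumeration over ``{0,1,2}^k`` -- no sampling.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    k = len(levels)
    g = _genotype_tuples(k)  # (T, k)
    P = hwe_probs(f)  # (F, 3)
    w = np.ones((f.size, g.shape[0]))
    for v in range(k):
        w *= P[:, g[:, v]]
    prod = np.ones((f.size, g.shape[0]))
    for kind, u, v in edges:
        if kind == KIND_MAIN:
            vals = np.abs(g[:, u] - g[:, v]).astype(float)
            mean = pair_mean(1.0, 1.0, f)
        else:
            vals = np.abs(g[:, u] * levels[u] - g[:, v] * levels[v]).astype(float)
            mean = pair_mean(levels[u], levels[v], f)
        prod *= vals[None, :] - mean[:, None]
    return np.einsum("ft,ft->f", w, prod)


# ---------------------------------------------------------------------------
# per-pair moment summaries


@dataclass(frozen=True)
class GenotypeMoments:
    """HWE moments of the genetic distance G_ij = |g_i - g_j| at one MAF."""

    f: float
    hwe: tuple
    mean_G: float
    var_G: float
    cov_G: float  # Cov(G_ij, G_ik), shared subject i

    def pattern(self, edges, f=None) -> float:
        """Centered cross-moment E[prod G~] for an arbitrary pattern."""
        levels = (1.0,) * (1 + max(max(u, v) for _, u, v in edges))
        return float(pattern_moment(edges, levels, self.f if f is None else f)[0])


@dataclass(frozen=True)
class DeltaMoments:
    """Environment-averaged HWE moments of Delta_ij = |g_i E_i - g_j E_j|.

    Averages are exact over the observed pairs/triples of environment
    values; genotype expectations are exact HWE enumerations.
    """

    f: float
    var_delta: float
    cov_delta: float       # Cov(Delta_ij, Delta_ik)
    cov_g_delta_same: float  # Cov(G_ij, Delta_ij)
    cov_g_delta_adj: float   # Cov(G_ij, Delta_ik)


def genotype_pair_moments(f: float) -> GenotypeMoments:
    """Exact HWE moments of G_ij = |g_i - g_j| and Cov(G_ij, G_ik)."""
    f = float(_check_maf(f))
    p = tuple(hwe_probs(f))
    mean = float(pair_mean(1.0, 1.0, f)[0])
    var = float(pattern_moment(((KIND_MAIN, 0, 1),) * 2, (1.0, 1.0), f)[0])
    cov = float(
        pattern_moment(((KIND_MAIN, 0, 1), (KIND_MAIN, 0, 2)), (1.0,) * 3, f)[0]
    )
    return GenotypeMoments(f=f, hwe=p, mean_G=mean, var_G=var, cov_G=cov)


def _level_pair_weights(env: np.ndarray):
    """Unique levels plus exact frequencies of ordered pairs and cherries."""
    levels, counts = np.unique(np.asarray(env, dtype=float), return_counts=True)
    return levels, counts


def delta_moments(f: float, env) -> DeltaMoments:
    """Environment-averaged moments of Delta (exact over observed E values)."""
    f = float(_check_maf(f))
    env = np.asarray(env, dtype=float)
    n = env.size
    levels, counts = _level_pair_weights(env)
    L = levels.size

    def m(edges, lv):
        return float(pattern_moment(edges, lv, f)[0])

    var = cov = cgd_same = cgd_adj = 0.0
    # ordered distinct pairs
    n_pairs = n * (n - 1)
    for a in range(L):
        for b in range(L):
            w = counts[a] * (counts[b] - (a == b))
            if w == 0:
                continue
            w /= n_pairs
            lv = (levels[a], levels[b])
            var += w * m(((KIND_INTER, 0, 1),) * 2, lv)
            cgd_same += w * m(((KIND_MAIN, 0, 1), (KIND_INTER, 0, 1)), lv)
    # ordered distinct triples (i; j, k) with i the shared subject
    n_triples = n * (n - 1) * (n - 2)
    for a in range(L):
        for b in range(L):
            for c in range(L):
                w = counts[a] * (counts[b] - (a == b)) * (
                    counts[c] - (a == c) - (b == c)
                )
                if w <= 0:
                    continue
                w /= n_triples
                lv = (levels[a], levels[b], levels[c])
                cov += w * m(((KIND_INTER, 0, 1), (KIND_INTER, 0, 2)), lv)
                cgd_adj += w * m(((KIND_MAIN, 0, 1), (KIND_INTER, 0, 2)), lv)
    return DeltaMoments(
        f=f,
        var_delta=var,
        cov_delta=cov,
        cov_g_delta_same=cgd_same,
        cov_g_delta_adj=cgd_adj,
    )


def score_variance(cd, gm: GenotypeMoments) -> float:
    """Null variance of S_M from the closed second-order decomposition.

    ``Var0(S_M | D) = N(N-1)/2 * Var(G) * mu2 + N(N-1)(N-2) * Cov(G_ij,G_ik) * mu3``

    This is an independent route from the generic pattern engine and is
    cross-checked against it (and against exact enumeration) in the tests.
    """
    n = cd.n
    return (
        n * (n - 1) / 2.0 * gm.var_G * cd.mu2
        + n * (n - 1) * (n - 2) * gm.cov_G * cd.mu3
    )


# ---------------------------------------------------------------------------
# generic engine


class MomentEngine:
    """Assembles central null moments of (S_M, S_I) for one study.

    Parameters
    ----------
    dprime
        Centered/residualized pair-value matrix (symmetric, zero diagonal).
    env
        Environment vector aligned to the matrix, or None for main-effect
        only analyses.  Environments with more than ``max_levels`` distinct
        values are discretized into ``max_levels`` quantile strata for the
        moment computation (scores themselves always use the exact values).
    """

    def __init__(self, dprime: np.ndarray, env=None, max_levels: int = 8):
        A = np.array(dprime, dtype=float)
        np.fill_diagonal(A, 0.0)
        self.A = A
        self.n = A.shape[0]
        if env is None:
            self.levels = np.array([1.0])
            member = np.zeros(self.n, dtype=int)
        else:
            env = np.asarray(env, dtype=float)
            if env.size != self.n:
                raise ValueError("environment vector not aligned to the matrix")
            uniq = np.unique(env)
            if uniq.size > max_levels:
                qs = np.quantile(env, np.linspace(0, 1, max_levels + 1)[1:-1])
                member = np.searchsorted(qs, env, side="left")
                self.levels = np.array(
                    [env[member == j].mean() for j in range(max_levels)]
                )
            else:
                self.levels = uniq
                member = np.searchsorted(uniq, env)
        self.member = member
        indicators = [
            (member == j).astype(float) for j in range(self.levels.size)
        ]
        self._counts = np.array([ind.sum() for ind in indicators])
        self._ds = DistinctSums(A, indicators)

    def central_moment(self, kinds, f) -> np.ndarray:
        """Central cross-moment E[prod S~_kind] over a MAF scalar/grid."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        total = np.zeros(f.size)
        nlev = self.levels.size
        for edges, count in edge_patterns(tuple(kinds)):
            k = 1 + max(max(u, v) for _, u, v in edges)
            untyped = tuple((u, v) for _, u, v in edges)
            for tau in iter_product(range(nlev), repeat=k):
                if any(self._counts[t] == 0 for t in tau):
                    continue
                D = self._ds.dsum(untyped, tau)
                if D == 0.0:
                    continue
                lv = tuple(self.levels[t] for t in tau)
                total += count * D * pattern_moment(edges, lv, f)
        return total / 2.0 ** len(kinds)

    def interaction_mean(self, f) -> np.ndarray:
        """Exact null mean E0[S_I] = sum_{i<j} a_ij E[Delta_ij | E_i, E_j].

        Nonzero in general when conditioning on a fixed environment vector,
        because pairs concordant in E at different levels share |E_i - E_j|
        but not E[Delta]; Z_I therefore standardizes S_I - E0[S_I].
        """
        f = np.atleast_1d(np.asarray(f, dtype=float))
        total = np.zeros(f.size)
        nlev = self.levels.size
        for a in range(nlev):
            for b in range(nlev):
                w = float(
                    self._ds.indicators[a] @ self.A @ self._ds.indicators[b]
                )
                if w != 0.0:
                    total += 0.5 * w * pair_mean(self.levels[a], self.levels[b], f)
        return total


def score_skew_kurt(cd, f, env=None):
    """Skewness and excess kurtosis of the standardized score at MAF ``f``.

    Main-effect score if ``env`` is None, interaction score otherwise.
    """
    engine = MomentEngine(cd.dprime, env)
    kind = KIND_MAIN if env is None else KIND_INTER
    var = engine.central_moment((kind,) * 2, f)
    e3 = engine.central_moment((kind,) * 3, f)
    e4 = engine.central_moment((kind,) * 4, f)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = e3 / var**1.5
        kappa = e4 / var**2 - 3.0
    if np.isscalar(f) or np.asarray(f).ndim == 0:
        return float(gamma[0]), float(kappa[0])
    return gamma, kappa


def scores_correlation(cd, f, env) -> float:
    """Null correlation rho = Cor0(Z_M, Z_I) at MAF ``f``, clamped to [-1, 1]."""
    engine = MomentEngine(cd.dprime, env)
    var_m = float(engine.central_moment((KIND_MAIN,) * 2, f)[0])
    var_i = float(engine.central_moment((KIND_INTER,) * 2, f)[0])
    if var_m <= 0.0 or var_i <= 0.0:
        raise ZeroDivisionError("score variance vanishes; SNP not testable")
    cov = float(engine.central_moment((KIND_MAIN, KIND_INTER), f)[0])
    return float(np.clip(cov / np.sqrt(var_m * var_i), -1.0, 1.0))


# ---------------------------------------------------------------------------
# assembled per-SNP moment sets


@dataclass
class NullMoments:
    """All null moments needed to test one SNP at MAF ``f``."""

    f: float
    var_M: float
    gamma_M: float
    kappa_M: float
    mean_I: float | None = None
    var_I: float | None = None
    gamma_I: float | None = None
    kappa_I: float | None = None
    cov_MI: float | None = None
    rho: float | None = None
    #: standardized central mixed moments E[Z~_M^a Z~_I^b]
    std_mixed: dict = field(default_factory=dict)

    @property
    def has_interaction(self) -> bool:
        return self.var_I is not None

    def combo_gamma_kappa(self, c1: float, c2: float):
        """Skewness/kurtosis of ``c1 Z_M + c2 Z_I`` (variance must be ~1)."""
        m3 = sum(
            comb(3, a) * c1**a * c2 ** (3 - a) * self.std_mixed[(a, 3 - a)]
            for a in range(4)
        )
        m4 = sum(
            comb(4, a) * c1**a * c2 ** (4 - a) * self.std_mixed[(a, 4 - a)]
            for a in range(5)
        )
        var = c1**2 + c2**2 + 2.0 * c1 * c2 * self.rho
        return m3 / var**1.5, m4 / var**2 - 3.0


def _assemble(f, arrays, with_env):
    """Build NullMoments from raw moment arrays evaluated at one f."""
    var_M = arrays[(2, 0)]
    e3_M, e4_M = arrays[(3, 0)], arrays[(4, 0)]
    nm = NullMoments(
        f=float(f),
        var_M=float(var_M),
        gamma_M=float(e3_M / var_M**1.5),
        kappa_M=float(e4_M / var_M**2 - 3.0),
    )
    if not with_env:
        return nm
    var_I = arrays[(0, 2)]
    if var_I <= 0 or var_M <= 0:
        nm.var_I = float(var_I)
        return nm
    cov = arrays[(1, 1)]
    sm, si = np.sqrt(var_M), np.sqrt(var_I)
    nm.mean_I = float(arrays["mean_I"])
    nm.var_I = float(var_I)
    nm.gamma_I = float(arrays[(0, 3)] / var_I**1.5)
    nm.kappa_I = float(arrays[(0, 4)] / var_I**2 - 3.0)
    nm.cov_MI = float(cov)
    nm.rho = float(np.clip(cov / (sm * si), -1.0, 1.0))
    nm.std_mixed = {
        (a, b): float(arrays[(a, b)] / sm**a / si**b)
        for (a, b) in MIXED_ORDERS
        if a + b >= 3
    }
    return nm


class NullMomentCalculator:
    """Exact null moments for one study (fixed pair values + environment)."""

    def __init__(self, cd, env=None):
        self.cd = cd
        self.env = None if env is None else np.asarray(env, dtype=float)
        self.engine = MomentEngine(cd.dprime, env)

    def _raw(self, f) -> dict:
        f = np.atleast_1d(np.asarray(f, dtype=float))
        _check_maf(f)
        eng = self.engine
        arrays = {}
        orders = MIXED_ORDERS if self.env is not None else [
            (a, 0) for a in (2, 3, 4)
        ]
        for a, b in orders:
            kinds = (KIND_MAIN,) * a + (KIND_INTER,) * b
            arrays[(a, b)] = eng.central_moment(kinds, f)
        if self.env is not None:
            arrays["mean_I"] = eng.interaction_mean(f)
        return arrays

    def at(self, f: float) -> NullMoments:
        arrays = self._raw(f)
        return _assemble(f, {k: v[0] for k, v in arrays.items()},
                         self.env is not None)

    def grid(self, grid=None) -> "NullMomentGrid":
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        return NullMomentGrid(grid, self._raw(grid), self.env is not None)


class NullMomentGrid:
    """MAF-grid precomputation with per-SNP linear interpolation.

    Raw moment arrays are tabulated once on the grid (the distance-structure
    sums are shared across the grid); a SNP's moments are linearly
    interpolated at its MAF and assembled into skewness/kurtosis terms.
    """

    def __init__(self, grid, arrays, with_env):
        self.grid = grid
        self.arrays = arrays
        self.with_env = with_env

    def at(self, f: float) -> NullMoments:
        f = float(f)
        vals = {k: float(np.interp(f, self.grid, v)) for k, v in self.arrays.items()}
        return _assemble(f, vals, self.with_env)
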