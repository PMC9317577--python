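"""Synthetic microbiome-GWAS data and the oracles that certify the analytics.

The generative model for pair distances is
``d_ij = alpha + betaM G_ij + betaE |E_i - E_j| + betaI Delta_ij + eps_ij``
with G_ij = |g_i - g_j| and Delta_ij = |g_i E_i - g_j E_j|; the residual
term arises implicitly from subject-level randomness so generated matrices
remain valid metrics.  Two community generators are provided:

* ``latent``: subject profiles from a multivariate normal; genotype
  (and genotype-by-environment) effects shift a latent axis; distances are
  Euclidean norms.
* ``dirichlet``: taxa proportions from a Dirichlet distribution whose
  log-concentrations shift with genotype (and genotype-by-environment);
  counts are multinomial at fixed sequencing depth; distances are
  Bray-Curtis.  The default community has a log-normal abundance profile
  spanning several orders of magnitude and moderate overdispersion, the
  regime where a few dominant taxa make pair distances right-skewed.

Under zero effects both reduce to exchangeable null matrices.

Two oracles certify the analytic null moments: ``exact_enumeration_oracle``
sums over all 3^N Hardy-Weinberg genotype vectors (N <= 8), and
``permutation_oracle`` redraws genotypes iid HWE at scale, holding the
distance matrix and environment fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .moments import hwe_probs
from .score import batch_scores

__all__ = [
    "SimulationDesign",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_distance_matrix",
    "replicate_subjects",
    "permutation_oracle",
    "exact_enumeration_oracle",
]


def simulate_genotypes(n: int, f: float, rng, size=None) -> np.ndarray:
    """iid Hardy-Weinberg dosages in {0,1,2} at MAF ``f``.

    ``size`` draws a (size, n) matrix of independent SNP vectors.
    """
    if not 0.0 < f <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(rng)
    p = hwe_probs(f)
    shape = n if size is None else (size, n)
    return rng.choice(3, size=shape, p=p)


def simulate_environment(n: int, rng, frequency: float = 0.5) -> np.ndarray:
    """Binary environment factor, independent of genotype."""
    rng = np.random.default_rng(rng)
    return (rng.random(n) < frequency).astype(float)


@dataclass
class SimulationDesign:
    """Study design for one synthetic dataset.

    Effect sizes are on the scale of the latent axis (``latent`` flavor) or
    of the log-concentration shift (``dirichlet`` flavor); zero effects give
    an exchangeable null.  Defaults mirror a rarefied 16S profile: 200 taxa
    with a log-normal base abundance profile (sd 2 on the log scale), total
    Dirichlet concentration 30, multinomial depth 10,000 reads.
    """

    n: int = 100
    maf: float = 0.2
    beta_m: float = 0.0
    beta_e: float = 0.0
    beta_i: float = 0.0
    env_frequency: float = 0.5
    continuous_env: bool = False
    flavor: str = "dirichlet"
    n_taxa: int = 200
    log_abundance_sd: float = 2.0
    concentration: float = 30.0
    depth: int = 10_000
    n_latent: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.flavor not in ("dirichlet", "latent"):
            raise ValueError(f"unknown flavor {self.flavor!r}")


@dataclass
class SimulationTruth:
    genotypes: np.ndarray
    environment: np.ndarray | None
    design: SimulationDesign
    extras: dict = field(default_factory=dict)


def _dirichlet_distances(design, g, env, rng):
    """Bray-Curtis distances of Dirichlet-multinomial communities."""
    base = rng.normal(0.0, design.log_abundance_sd, size=design.n_taxa)
    # mean-zero taxa contrast carrying the genetic / GxE shift
    contrast = np.zeros(design.n_taxa)
    affected = rng.choice(design.n_taxa, size=max(2, design.n_taxa // 10),
                          replace=False)
    contrast[affected] = rng.choice([-1.0, 1.0], size=affected.size)
    shift = np.zeros((design.n, design.n_taxa))
    shift += design.beta_m * np.outer(g, contrast)
    if env is not None:
        env_axis = np.zeros(design.n_taxa)
        env_axis[rng.choice(design.n_taxa, size=max(2, design.n_taxa // 10),
                            replace=False)] = 1.0
        shift += design.beta_e * np.outer(env, env_axis)
        shift += design.beta_i * np.outer(g * env, contrast)
    logits = base[None, :] + shift
    props = np.exp(logits - logits.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    counts = np.empty_like(props)
    for i in range(design.n):
        alpha = design.concentration * design.n_taxa * props[i]
        p = rng.dirichlet(np.maximum(alpha, 1e-8))
        counts[i] = rng.multinomial(design.depth, p)
    return squareform(pdist(counts, metric="braycurtis"))


def _latent_distances(design, g, env, rng):
    z = rng.normal(size=(design.n, design.n_latent))
    z[:, 0] += design.beta_m * g
    if env is not None:
        z[:, 1 % design.n_latent] += design.beta_e * env
        z[:, 0] += design.beta_i * g * env
    return squareform(pdist(z, metric="euclidean"))


def simulate_distance_matrix(design: SimulationDesign, rng=None):
    """Generate one distance matrix plus the truth record used to plant it."""
    rng = np.random.default_rng(design.seed if rng is None else rng)
    g = simulate_genotypes(design.n, design.maf, rng)
    needs_env = design.beta_e != 0.0 or design.beta_i != 0.0 or design.continuous_env
    env = None
    if needs_env or design.env_frequency is not None:
        if design.continuous_env:
            env = rng.normal(size=design.n)
        else:
            env = simulate_environment(design.n, rng, design.env_frequency)
    if design.flavor == "dirichlet":
        d = _dirichlet_distances(design, g, env, rng)
    else:
        d = _latent_distances(design, g, env, rng)
    ids = [f"S{i + 1}" for i in range(design.n)]
    dm = DistanceMatrix(d, ids=ids)
    return dm, SimulationTruth(genotypes=g, environment=env, design=design)


def replicate_subjects(dm: DistanceMatrix, k: int) -> DistanceMatrix:
    """Grow a matrix ``k``-fold by subject replication, preserving structure.

    Every subject appears ``k`` times; distances between different subjects
    are inherited, while pairs of copies of the *same* subject are placed at
    the overall mean distance so that, after centering, duplicated-subject
    pairs carry exactly zero weight.  (Setting copy pairs to distance zero
    instead would inject N artificial extreme pairs that dominate the third
    and fourth moments.)  All per-tuple-normalized distance-structure sums
    are preserved up to O(1/N), which makes this the natural family for
    studying how skewness (~ N^-1/2) and kurtosis (~ 1/N) decay with sample
    size on a fixed community structure.
    """
    d = dm.data
    n = d.shape[0]
    mean = d.sum() / (n * (n - 1))
    out = np.tile(d, (k, k))
    for a in range(k):
        for b in range(k):
            if a != b:
                np.fill_diagonal(out[a * n:(a + 1) * n, b * n:(b + 1) * n], mean)
    np.fill_diagonal(out, 0.0)
    ids = [f"{s}_r{c + 1}" for c in range(k) for s in dm.ids]
    return DistanceMatrix(out, ids=ids)


# ---------------------------------------------------------------------------
# oracles


def _moments_from_samples(s: np.ndarray) -> dict:
    c = s - s.mean()
    var = float((c**2).mean())
    return {
        "mean": float(s.mean()),
        "var": var,
        "gamma": float((c**3).mean() / var**1.5),
        "kappa": float((c**4).mean() / var**2 - 3.0),
    }


def permutation_oracle(cd, f: float, env=None, reps: int = 10_000, rng=None,
                       batch: int = 20_000) -> dict:
    """Empirical null moments of (S_M, S_I) from iid HWE genotype redraws.

    The distance structure (and environment) stay fixed; only genotypes are
    redrawn, matching the null model of the analytic moments.  Returns
    empirical mean/variance/skewness/kurtosis (and the S_M-S_I correlation
    when an environment is supplied) plus the raw score samples.
    """
    rng = np.random.default_rng(rng)
    A = cd.dprime
    n = A.shape[0]
    sm = np.empty(reps)
    si = np.empty(reps) if env is not None else None
    env = None if env is None else np.asarray(env, dtype=float)
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        G = simulate_genotypes(n, f, rng, size=b)
        sm[done:done + b] = batch_scores(A, G)
        if env is not None:
            si[done:done + b] = batch_scores(A, G * env[None, :])
        done += b
    out = {"reps": reps, "S_M": sm, "main": _moments_from_samples(sm)}
    if env is not None:
        out["S_I"] = si
        out["interaction"] = _moments_from_samples(si)
        out["rho"] = float(np.corrcoef(sm, si)[0, 1])
    return out


def exact_enumeration_oracle(cd, f: float, env=None) -> dict:
    """Exact null moments by enumeration over all 3^N genotype vectors.

    Only feasible for N <= 8 (3^8 = 6561 vectors); every analytic moment
    must match these values to numerical precision.
    """
    A = cd.dprime
    n = A.shape[0]
    if n > 8:
        raise ValueError("exact enumeration limited to N <= 8 subjects")
    codes = np.indices((3,) * n).reshape(n, -1).T  # (3^n, n)
    p = hwe_probs(f)
    w = p[codes].prod(axis=1)
    iu = np.triu_indices(n, k=1)
    a = A[iu]

    def score_samples(vals):
        return np.abs(vals[:, iu[0]] - vals[:, iu[1]]) @ a

    def wmoments(s):
        mean = float(w @ s)
        c = s - mean
        var = float(w @ c**2)
        out = {
            "mean": mean,
            "var": var,
            "mu3": float(w @ c**3),
            "mu4": float(w @ c**4),
            "gamma": float(w @ c**3 / var**1.5) if var > 0 else np.nan,
            "kappa": float(w @ c**4 / var**2 - 3.0) if var > 0 else np.nan,
        }
        return out, c

    sm = score_samples(codes.astype(float))
    out = {"main": wmoments(sm)[0]}
    main_c = sm - out["main"]["mean"]
    if env is not None:
        env = np.asarray(env, dtype=float)
        si = score_samples(codes * env[None, :])
        inter, inter_c = wmoments(si)
        out["interaction"] = inter
        cov = float(w @ (main_c * inter_c))
        out["cov"] = cov
        out["rho"] = cov / np.sqrt(out["main"]["var"] * inter["var"])
        out["mixed"] = {
            (i, j): float(w @ (main_c**i * inter_c**j))
            for i in range(5) for j in range(5) if 2 <= i + j <= 4
        }
    return out
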