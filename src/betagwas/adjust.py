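"""Covariate and environment adjustment of distance matrices.

Covariate main effects are projected out of the distance structure with a
distance-based redundancy (dbRDA) construction: the squared distances are
double-centered into a Gower matrix, the covariate projector is applied on
both sides, and residual distances are reconstructed from the residual
Gower form.  The environment main effect for the interaction null is
removed by ordinary least squares of d_ij on |E_i - E_j| across pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .distance import CenteredDistances, center_distances

__all__ = ["dbrda_residualize", "interaction_null_residuals", "CollinearityError"]


class CollinearityError(ValueError):
    """The covariate design matrix is rank deficient."""


def _design(X, n):
    if X is None:
        return np.ones((n, 1)), ["(intercept)"]
    if isinstance(X, pd.DataFrame):
        names = ["(intercept)"] + [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = ["(intercept)"] + [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != n:
        raise ValueError("covariate rows not aligned to distance matrix")
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values after alignment")
    # constant columns live in the intercept span: drop rather than error
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 1e-12]
    X = X[:, keep]
    names = ["(intercept)"] + [names[1 + j] for j in keep]
    return np.column_stack([np.ones(n), X]), names


def dbrda_residualize(D: DistanceMatrix, X=None) -> DistanceMatrix:
    """Residualize a distance matrix on covariates.

    Computes the Gower matrix ``G = -1/2 C (d o d) C`` with
    ``C = I - 11'/N``, projects out ``span(1, X)`` on both sides,
    ``G_res = (I - H) G (I - H)``, and reconstructs residual distances
    ``d'_ij = sqrt(max(G_ii + G_jj - 2 G_ij, 0))``.  With no covariates the
    input distances are returned unchanged (up to numerical noise) whenever
    they are Euclidean-embeddable.
    """
    d = D.data
    n = d.shape[0]
    M, names = _design(X, n)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offending columns via incremental rank
        bad, cur = [], np.ones((n, 0))
        for j in range(M.shape[1]):
            trial = np.column_stack([cur, M[:, j]])
            if np.linalg.matrix_rank(trial) > cur.shape[1]:
                cur = trial
            else:
                bad.append(names[j])
        raise CollinearityError(f"collinear covariate columns: {', '.join(bad)}")
    C = np.eye(n) - 1.0 / n
    G = -0.5 * C @ (d * d) @ C
    Q, _ = np.linalg.qr(M)
    H = Q @ Q.T
    P = np.eye(n) - H
    Gres = P @ G @ P
    diag = np.diag(Gres)
    d2 = diag[:, None] + diag[None, :] - 2.0 * Gres
    d2 = np.clip(d2, 0.0, None)
    out = np.sqrt(d2)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids=D.ids)


def interaction_null_residuals(D: DistanceMatrix, env) -> CenteredDistances:
    """Pair-level OLS removal of the environment main effect.

    Fits ``d_ij = alpha + beta_E |E_i - E_j|`` over all N(N-1)/2 pairs and
    returns the residual pair values (which sum to zero) as a
    :class:`CenteredDistances`.  The fitted intercept/slope are stored in
    ``cd.meta``.  A constant environment degenerates to plain centering.
    """
    if isinstance(D, DistanceMatrix):
        d, ids = D.data, tuple(D.ids)
    else:
        d = np.asarray(D, dtype=float)
        ids = tuple(range(d.shape[0]))
    env = np.asarray(env, dtype=float)
    n = d.shape[0]
    if env.size != n:
        raise ValueError("environment vector not aligned to distance matrix")
    iu = np.triu_indices(n, k=1)
    y = d[iu]
    x = np.abs(env[:, None] - env[None, :])[iu]
    if np.ptp(x) < 1e-12:
        warnings.warn(
            "environment is constant across subjects; falling back to "
            "intercept-only centering",
            stacklevel=2,
        )
        cd = center_distances(D)
        cd.meta.update(alpha=float(y.mean()), beta_env=0.0)
        return cd
    M = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    R = np.zeros_like(d)
    R[iu] = resid
    R = R + R.T
    cd = CenteredDistances(dprime=R, ids=ids)
    cd.meta.update(alpha=float(coef[0]), beta_env=float(coef[1]))
    return cd
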