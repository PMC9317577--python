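"""Reading, validating and centering microbiome beta-diversity distance matrices.

Distances arrive as square labeled text matrices (QIIME / vegan exports,
tab- or comma-delimited, first row and column holding sample identifiers) or
as lower-triangle PHYLIP files.  The in-memory container is scikit-bio's
:class:`skbio.stats.distance.DistanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .patterns import DistinctSums, edge_patterns, pattern_name, KIND_MAIN

__all__ = [
    "DistanceFormatError",
    "read_distance_matrix",
    "write_distance_matrix",
    "validate_distance_matrix",
    "CenteredDistances",
    "center_distances",
]

#: relative asymmetry tolerated in text input before declaring a format error
ASYMMETRY_RTOL = 1e-8


class DistanceFormatError(ValueError):
    """A distance-matrix file violates the format contract."""


def _parse_phylip_lower(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 1 or not first[0].isdigit():
            raise DistanceFormatError(f"{path}: not a PHYLIP matrix header")
        n = int(first[0])
        labels, rows = [], []
        for i in range(n):
            parts = fh.readline().split()
            if len(parts) != i + 1:
                raise DistanceFormatError(
                    f"{path}: ragged PHYLIP row for sample {len(labels) + 1}"
                )
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    d = np.zeros((n, n))
    for i, row in enumerate(rows):
        d[i, : len(row)] = row
    d = d + d.T
    return pd.DataFrame(d, index=labels, columns=labels)


def _parse_square(path, sep) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    except Exception as exc:  # ragged rows, bad tokens, ...
        raise DistanceFormatError(f"{path}: cannot parse as a labeled matrix ({exc})")
    if df.shape[0] != df.shape[1]:
        raise DistanceFormatError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise DistanceFormatError(f"{path}: row labels do not match column labels")
    return df


def validate_distance_matrix(d: np.ndarray, labels, source="<memory>") -> DistanceMatrix:
    """Validate raw values and return a (symmetrized) DistanceMatrix."""
    d = np.asarray(d, dtype=float)
    labels = [str(x) for x in labels]
    n = d.shape[0]
    if len(set(labels)) != n:
        raise DistanceFormatError(f"{source}: duplicate sample labels")
    if n < 3:
        raise DistanceFormatError(f"{source}: need at least 3 subjects, got {n}")
    if not np.all(np.isfinite(d)):
        i, j = np.argwhere(~np.isfinite(d))[0]
        raise DistanceFormatError(
            f"{source}: non-finite entry at ({labels[i]}, {labels[j]})"
        )
    if np.any(d < 0):
        i, j = np.argwhere(d < 0)[0]
        raise DistanceFormatError(
            f"{source}: negative distance {d[i, j]!r} at ({labels[i]}, {labels[j]})"
        )
    scale = float(np.abs(d).max()) or 1.0
    if np.any(np.abs(np.diag(d)) > ASYMMETRY_RTOL * scale):
        i = int(np.argmax(np.abs(np.diag(d))))
        raise DistanceFormatError(
            f"{source}: nonzero diagonal {d[i, i]!r} for sample {labels[i]}"
        )
    asym = np.abs(d - d.T)
    worst = float(asym.max())
    if worst > ASYMMETRY_RTOL * scale:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise DistanceFormatError(
            f"{source}: asymmetric at ({labels[i]}, {labels[j]}): "
            f"{d[i, j]!r} vs {d[j, i]!r}"
        )
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


def read_distance_matrix(path, dialect: str = "auto") -> DistanceMatrix:
    """Read a beta-diversity matrix file.

    ``dialect`` is one of ``auto``, ``tsv``, ``csv`` or ``phylip``
    (lower-triangle).  Label order is preserved from the file.
    """
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        toks = first.split()
        dialect = (
            "phylip" if len(toks) == 1 and toks[0].isdigit()
            else ("csv" if "," in first else "tsv")
        )
    if dialect == "phylip":
        df = _parse_phylip_lower(path)
    elif dialect in ("tsv", "csv"):
        df = _parse_square(path, "\t" if dialect == "tsv" else ",")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return validate_distance_matrix(df.to_numpy(dtype=float), df.index, source=str(path))


def write_distance_matrix(dm: DistanceMatrix, path, dialect: str = "tsv",
                          precision: int = 10) -> None:
    sep = "\t" if dialect == "tsv" else ","
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep=sep, float_format=f"%.{precision}g")


# ---------------------------------------------------------------------------


@dataclass
class CenteredDistances:
    """Centered pair values d'_ij plus the distance-structure sums.

    ``mu2`` and ``mu3`` are the second/third-order sums entering the score
    variance; higher-order pattern sums (for skewness and kurtosis) are
    computed lazily through the pattern engine and cached.
    """

    dprime: np.ndarray
    ids: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        A = np.array(self.dprime, dtype=float)
        np.fill_diagonal(A, 0.0)
        self.dprime = A
        n = A.shape[0]
        self.n = n
        if n < 3:
            raise ValueError("mu3 undefined: need at least 3 subjects")
        self.mu2 = float(2.0 / (n * (n - 1)) * (A**2).sum() / 2.0)
        r = A.sum(axis=1)
        cherry = float(((r**2).sum() - (A**2).sum()))  # ordered (i; j != k)
        self.mu3 = float(cherry / (n * (n - 1) * (n - 2)))
        self._ds = DistinctSums(A, [np.ones(n)])

    def pattern_sums(self, order: int = 3) -> dict:
        """Named distinct-tuple sums of d' products for patterns of ``order`` edges."""
        out = {}
        for edges, _count in edge_patterns((KIND_MAIN,) * order):
            untyped = tuple((u, v) for _, u, v in edges)
            k = 1 + max(max(e) for e in untyped)
            out[pattern_name(untyped)] = self._ds.dsum(untyped, (0,) * k)
        return out

    def distinct_sum(self, untyped_edges) -> float:
        k = 1 + max(max(e) for e in untyped_edges)
        return self._ds.dsum(tuple(untyped_edges), (0,) * k)


def center_distances(D) -> CenteredDistances:
    """Center pair distances: d'_ij = d_ij - mean over the N(N-1)/2 pairs."""
    if isinstance(D, DistanceMatrix):
        d, ids = D.data, tuple(D.ids)
    else:
        d = np.asarray(D, dtype=float)
        ids = tuple(range(d.shape[0]))
    n = d.shape[0]
    if n < 3:
        raise ValueError("mu3 undefined: need at least 3 subjects")
    mean = d.sum() / (n * (n - 1))  # off-diagonal mean (diagonal is zero)
    dp = d - mean
    np.fill_diagonal(dp, 0.0)
    return CenteredDistances(dprime=dp, ids=ids)
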