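"""Genome-wide scan: the model/results layer tying the pieces together.

:class:`DistanceAssociation` is the model object: it holds the distance
matrix, covariates and (optionally) the environment variable, prepares the
residualized pair values and the MAF-grid null moments once, and then tests
SNPs one at a time in O(N^2) each.  ``fit`` streams a PLINK panel and
returns a :class:`ScanResults` carrying the association table, skip log and
genomic-control diagnostics.

Main-effect statistics are computed on the covariate-adjusted centered
distances; the interaction and joint statistics are computed on the
environment-residualized matrix (including the joint test's own Z_M, whose
null moments refer to that matrix).  SNPs with missing genotypes are
handled exactly: the affected subjects are dropped, the pair values are
re-residualized on the reduced subject set, and moments are recomputed at
the SNP's MAF (cached per missingness pattern).
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from skbio.stats.distance import DistanceMatrix

from .adjust import dbrda_residualize, interaction_null_residuals
from .distance import center_distances, read_distance_matrix
from .moments import NullMomentCalculator
from .plink import open_plink, snp_maf
from .score import (
    JointTestGeometry,
    joint_p_asymptotic,
    p_joint_corrected,
    score_interaction,
    score_main,
)
from .tail import p_upper_corrected

__all__ = [
    "AssocRecord",
    "DistanceAssociation",
    "ScanResults",
    "ScanConfig",
    "run_scan",
    "qq_lambda",
]

GENOME_WIDE = 5e-8


@dataclass
class AssocRecord:
    """Per-SNP association output."""

    snp: str
    chrom: str
    pos: int
    maf: float
    n_eff: int
    s_m: float | None = None
    z_m: float | None = None
    gamma_m: float | None = None
    kappa_m: float | None = None
    p_asym_m: float | None = None
    p_adj_m: float | None = None
    s_i: float | None = None
    z_i: float | None = None
    gamma_i: float | None = None
    kappa_i: float | None = None
    p_asym_i: float | None = None
    p_adj_i: float | None = None
    rho: float | None = None
    q_stat: float | None = None
    region: str | None = None
    p_asym_joint: float | None = None
    p_adj_joint: float | None = None
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


class _SubsetContext:
    """Residualized pair values + moment calculators for one subject subset."""

    def __init__(self, d_adj: np.ndarray, ids, env, use_grid, grid=None):
        self.cd_main = center_distances(DistanceMatrix(d_adj, ids=list(ids)))
        self.calc_main = NullMomentCalculator(self.cd_main)
        self.env = env
        if env is not None:
            self.cd_int = interaction_null_residuals(
                DistanceMatrix(d_adj, ids=list(ids)), env
            )
            self.calc_int = NullMomentCalculator(self.cd_int, env)
        else:
            self.cd_int = self.calc_int = None
        self.grid_main = self.calc_main.grid(grid) if use_grid else None
        self.grid_int = (
            self.calc_int.grid(grid) if use_grid and env is not None else None
        )

    def moments(self, f):
        if self.grid_main is not None:
            nm_main = self.grid_main.at(f)
            nm_int = self.grid_int.at(f) if self.grid_int is not None else None
        else:
            nm_main = self.calc_main.at(f)
            nm_int = self.calc_int.at(f) if self.calc_int is not None else None
        return nm_main, nm_int


class DistanceAssociation:
    """Score-test model for SNP association with beta-diversity distances.

    Parameters
    ----------
    distance
        An ``skbio`` DistanceMatrix (or path to a distance-matrix file).
    covariates
        Optional DataFrame indexed by sample ID; its columns are projected
        out of the distance structure before testing.
    environment
        Optional environment variable: a column name of ``covariates`` or a
        Series indexed by sample ID.  Enables the interaction and joint
        tests.  When named, the column is removed from the covariate set
        (its main effect is handled by the pair-level null regression).
    maf_min
        SNPs below this minor-allele frequency are skipped (default 0.05).
    use_grid
        Precompute null moments on a MAF grid (default) instead of exactly
        per SNP.
    """

    def __init__(self, distance, covariates=None, environment=None,
                 maf_min: float = 0.05, use_grid: bool = True,
                 grid_step: float = 0.005, min_subjects: int = 20):
        if isinstance(distance, (str,)):
            distance = read_distance_matrix(distance)
        self.distance = distance
        if not 0.0 <= maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        self.covariates = covariates
        self.environment = environment
        self.maf_min = maf_min
        self.use_grid = use_grid
        self.grid = np.round(np.arange(grid_step, 0.5 + 1e-9, grid_step), 9)
        self.min_subjects = min_subjects
        self._ctx_cache: dict = {}
        self._aligned = None

    # -- alignment -------------------------------------------------------

    def _align(self, panel_ids):
        dm_ids = list(self.distance.ids)
        panel_set = set(panel_ids)
        ids = [s for s in dm_ids if s in panel_set]
        dropped_dm = len(dm_ids) - len(ids)
        if not ids:
            raise ValueError("no overlapping samples between distance matrix "
                             "and genotype panel")
        if len(ids) < self.min_subjects:
            print(f"warning: only {len(ids)} overlapping subjects; "
                  "results will be unstable", file=sys.stderr)
        cov = self.covariates
        env_name = None
        env = self.environment
        if isinstance(env, str):
            env_name = env
            if cov is None or env not in cov.columns:
                raise ValueError(f"environment column {env!r} not in covariates")
            env = cov[env_name]
            cov = cov.drop(columns=[env_name])
        if cov is not None:
            missing = [s for s in ids if s not in cov.index]
            if missing:
                ids = [s for s in ids if s in cov.index]
            cov = cov.loc[ids]
        if env is not None and not isinstance(env, np.ndarray):
            env = pd.Series(env).loc[ids].to_numpy(dtype=float)
        elif env is not None:
            env = np.asarray(env, dtype=float)
        dm = self.distance.filter(ids)
        d_adj = dbrda_residualize(dm, cov).data if cov is not None and cov.shape[1] else dm.data
        self._aligned = {
            "ids": ids,
            "index_of": {s: i for i, s in enumerate(ids)},
            "d_adj": d_adj,
            "env": env,
            "dropped_from_distance": dropped_dm,
        }
        self._ctx_cache.clear()
        return self._aligned

    def _context(self, mask=None) -> _SubsetContext:
        al = self._aligned
        key = None if mask is None else mask.tobytes()
        ctx = self._ctx_cache.get(key)
        if ctx is None:
            if mask is None:
                d = al["d_adj"]
                ids = al["ids"]
                env = al["env"]
                use_grid = self.use_grid
            else:
                idx = np.flatnonzero(mask)
                d = al["d_adj"][np.ix_(idx, idx)]
                ids = [al["ids"][i] for i in idx]
                env = None if al["env"] is None else al["env"][idx]
                use_grid = False  # exact moments at the SNP's own MAF
            ctx = _SubsetContext(d, ids, env, use_grid, self.grid)
            self._ctx_cache[key] = ctx
        return ctx

    # -- per-SNP test ----------------------------------------------------

    def test_snp(self, g, snp="snp", chrom="0", pos=0) -> AssocRecord:
        """Test one aligned dosage vector ({0,1,2}, negative = missing)."""
        if self._aligned is None:
            raise RuntimeError("model not aligned; call fit() or align_to()")
        g = np.asarray(g)
        f, n_eff = snp_maf(g)
        rec = AssocRecord(snp=snp, chrom=str(chrom), pos=int(pos),
                          maf=f, n_eff=n_eff)
        if f <= 0.0:
            rec.skip_reason = "monomorphic"
            return rec
        if f < self.maf_min:
            rec.skip_reason = f"maf<{self.maf_min}"
            return rec
        mask = g >= 0
        if mask.all():
            ctx = self._context(None)
            gg = g.astype(float)
        else:
            if mask.sum() < 3:
                rec.skip_reason = "too few genotyped subjects"
                return rec
            ctx = self._context(mask)
            gg = g[mask].astype(float)
        nm_main, nm_int = ctx.moments(f)
        if nm_main.var_M <= 0:
            rec.skip_reason = "nonpositive null variance"
            return rec
        rec.s_m = score_main(ctx.cd_main, gg)
        rec.z_m = rec.s_m / np.sqrt(nm_main.var_M)
        rec.gamma_m, rec.kappa_m = nm_main.gamma_M, nm_main.kappa_M
        rec.p_asym_m = float(norm.sf(rec.z_m))
        rec.p_adj_m = p_upper_corrected(rec.z_m, rec.gamma_m, rec.kappa_m)
        if ctx.env is None:
            return rec
        env = ctx.env
        if np.ptp(env) < 1e-12:
            rec.skip_reason = "degenerate environment"
            return rec
        if nm_int is None or nm_int.var_I is None or nm_int.var_I <= 0:
            rec.skip_reason = "nonpositive interaction variance"
            return rec
        rec.s_i = score_interaction(ctx.cd_int, gg, env)
        rec.z_i = (rec.s_i - nm_int.mean_I) / np.sqrt(nm_int.var_I)
        rec.gamma_i, rec.kappa_i = nm_int.gamma_I, nm_int.kappa_I
        rec.p_asym_i = float(norm.sf(rec.z_i))
        rec.p_adj_i = p_upper_corrected(rec.z_i, rec.gamma_i, rec.kappa_i)
        rec.rho = nm_int.rho
        if abs(rec.rho) >= 1.0 - 1e-8:
            rec.skip_reason = "degenerate joint geometry"
            return rec
        geom = JointTestGeometry.from_rho(rec.rho)
        # the joint test's Z_M lives on the environment-residualized matrix
        z_m_res = score_main(ctx.cd_int, gg) / np.sqrt(nm_int.var_M)
        rec.q_stat = float(geom.qvalue(z_m_res, rec.z_i))
        rec.region = f"A{geom.classify(z_m_res, rec.z_i)}"
        rec.p_asym_joint = float(joint_p_asymptotic(z_m_res, rec.z_i, geom))
        rec.p_adj_joint = float(p_joint_corrected(z_m_res, rec.z_i, geom, nm_int))
        return rec

    # -- scanning --------------------------------------------------------

    def align_to(self, sample_ids):
        """Align the model to a genotype panel's sample order."""
        return self._align(sample_ids)

    def fit(self, panel, progress: bool = False) -> "ScanResults":
        """Stream a PLINK panel (object or path prefix) and test every SNP."""
        if isinstance(panel, str):
            panel = open_plink(panel)
        t0 = time.time()
        al = self._align(panel.sample_ids)
        order = [panel.sample_ids.index(s) for s in al["ids"]]
        order = np.asarray(order)
        records = []
        for meta, dosages in panel:
            rec = self.test_snp(dosages[order], snp=meta.snp,
                                chrom=meta.chrom, pos=meta.pos)
            records.append(rec)
            if progress and len(records) % 1000 == 0:
                print(f"  {len(records)} SNPs", file=sys.stderr)
        return ScanResults(self, records, n_subjects=len(al["ids"]),
                           elapsed=time.time() - t0,
                           dropped=al["dropped_from_distance"])


# ---------------------------------------------------------------------------


def qq_lambda(pvalues):
    """QQ coordinates (-log10 expected, observed) and genomic-control lambda.

    Lambda is the median of the implied chi-square(1) statistics over the
    chi-square(1) median, so bulk inflation reads as lambda > 1 while pure
    tail miscalibration leaves lambda at 1.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    if n < 100:
        raise ValueError("need at least 100 p-values for a QQ summary")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    z = norm.isf(np.clip(p, 1e-300, 1.0 - 1e-16))
    lam = float(np.median(z**2) / chi2.median(1))
    return expected[::-1], observed[::-1], lam


@dataclass
class ScanResults:
    """Association table plus scan-level diagnostics."""

    model: DistanceAssociation
    records: list
    n_subjects: int
    elapsed: float
    dropped: int = 0
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        if self._table is None:
            rows = [vars(r).copy() for r in self.records if not r.skipped]
            self._table = pd.DataFrame(rows).drop(columns=["skip_reason"],
                                                  errors="ignore")
        return self._table

    @property
    def skipped(self):
        return [(r.snp, r.skip_reason) for r in self.records if r.skipped]

    def lambda_gc(self, column: str = "p_adj_m") -> float:
        return qq_lambda(self.table[column].to_numpy())[2]

    def qq_table(self, column: str = "p_adj_m") -> pd.DataFrame:
        exp, obs, _ = qq_lambda(self.table[column].to_numpy())
        return pd.DataFrame({"expected_neglog10": exp, "observed_neglog10": obs})

    def n_genomewide(self, column: str) -> int:
        if column not in self.table:
            return 0
        return int((self.table[column] < GENOME_WIDE).sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            "Distance-association scan",
            f"  subjects analyzed: {self.n_subjects}"
            + (f" ({self.dropped} distance-matrix samples unmatched)"
               if self.dropped else ""),
            f"  SNPs tested: {len(t)}  skipped: {len(self.skipped)}",
            f"  elapsed: {self.elapsed:.1f} s",
        ]
        if len(t) >= 100:
            lines.append(f"  genomic-control lambda (adjusted main): "
                         f"{self.lambda_gc():.3f}")
        lines.append(
            "  genome-wide (p < 5e-08) before/after correction: "
            f"{self.n_genomewide('p_asym_m')}/{self.n_genomewide('p_adj_m')}"
        )
        if "p_adj_joint" in t.columns and t["p_adj_joint"].notna().any():
            lines.append(
                "  joint test genome-wide before/after: "
                f"{self.n_genomewide('p_asym_joint')}/"
                f"{self.n_genomewide('p_adj_joint')}"
            )
        return "\n".join(lines)

    def to_tsv(self, prefix: str) -> None:
        """Write the association table, QQ table and run log."""
        t = self.table.copy()
        for c in t.columns:
            if c.startswith("p_"):
                t[c] = t[c].map(lambda v: f"{v:.6e}" if pd.notna(v) else "NA")
        t.insert(len(t.columns), "genome_wide",
                 (self.table["p_adj_m"] < GENOME_WIDE).map({True: "Y", False: "N"}))
        t.to_csv(f"{prefix}.assoc.tsv", sep="\t", index=False,
                 float_format="%.6g", na_rep="NA")
        if len(self.table) >= 100:
            self.qq_table().to_csv(f"{prefix}.qq.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        with open(f"{prefix}.log", "w") as fh:
            fh.write(self.summary() + "\n")
            if self.skipped:
                fh.write("\nskipped SNPs:\n")
                for snp, reason in self.skipped:
                    fh.write(f"  {snp}\t{reason}\n")


# ---------------------------------------------------------------------------


@dataclass
class ScanConfig:
    """File-level configuration for a command-line scan."""

    distance_path: str
    plink_prefix: str
    covariate_path: str | None = None
    covariate_columns: tuple = ()
    environment: str | None = None
    maf_min: float = 0.05
    grid_step: float = 0.005
    out_prefix: str = "betagwas"
    seed: int = 0


def run_scan(config: ScanConfig) -> ScanResults:
    """Run a full scan from file paths; returns the results object."""
    dm = read_distance_matrix(config.distance_path)
    cov = None
    if config.covariate_path:
        cov = pd.read_csv(config.covariate_path, sep="\t", index_col=0)
        cov.index = cov.index.astype(str)
        keep = list(config.covariate_columns)
        if config.environment and config.environment not in keep:
            keep.append(config.environment)
        if keep:
            cov = cov[keep]
    model = DistanceAssociation(
        dm, covariates=cov, environment=config.environment,
        maf_min=config.maf_min, grid_step=config.grid_step,
    )
    results = model.fit(config.plink_prefix)
    results.to_tsv(config.out_prefix)
    return results
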