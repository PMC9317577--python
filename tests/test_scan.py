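"""End-to-end scan behavior: model/results objects, files, CLI, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from betagwas import (
    DistanceAssociation,
    SimulationDesign,
    qq_lambda,
    simulate_distance_matrix,
    simulate_environment,
    simulate_genotypes,
    write_distance_matrix,
    write_plink,
)
from betagwas.cli import main as cli_main


def build_panel(tmp_path, dm, n_snps, rng, planted=None):
    n = len(dm.ids)
    mafs = rng.uniform(0.05, 0.5, n_snps)
    G = np.vstack([simulate_genotypes(n, f, rng) for f in mafs])
    if planted is not None:
        G[0] = planted
    prefix = str(tmp_path / "geno")
    write_plink(prefix, G, sample_ids=list(dm.ids))
    return prefix, G


@pytest.fixture(scope="module")
def null_scan(tmp_path_factory, community_matrix_100):
    tmp = tmp_path_factory.mktemp("scan")
    rng = np.random.default_rng(12)
    prefix, _ = build_panel(tmp, community_matrix_100, 1200, rng)
    model = DistanceAssociation(community_matrix_100, maf_min=0.05)
    return model.fit(prefix)


class TestScan:
    def test_null_scan_is_calibrated(self, null_scan):
        t = null_scan.table
        # a few drawn SNPs fall under the MAF filter and are skipped
        assert len(t) + len(null_scan.skipped) == 1200 and len(t) > 1100
        lam = null_scan.lambda_gc()
        assert 0.9 < lam < 1.1
        # adjusted p-values behave uniformly in the bulk
        frac = (t.p_adj_m < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / len(t)))

    def test_deterministic_output_files(self, null_scan, tmp_path):
        null_scan.to_tsv(str(tmp_path / "a"))
        null_scan.to_tsv(str(tmp_path / "b"))
        assert (tmp_path / "a.assoc.tsv").read_bytes() == \
               (tmp_path / "b.assoc.tsv").read_bytes()
        assert (tmp_path / "a.qq.tsv").exists()
        assert "lambda" in (tmp_path / "a.log").read_text()

    def test_planted_effect_tops_the_scan(self, tmp_path):
        rng = np.random.default_rng(13)
        dm, truth = simulate_distance_matrix(
            SimulationDesign(n=150, maf=0.3, beta_m=1.0, flavor="latent", seed=14))
        prefix, _ = build_panel(tmp_path, dm, 150, rng, planted=truth.genotypes)
        res = DistanceAssociation(dm).fit(prefix)
        t = res.table
        assert t.loc[t.p_adj_m.idxmin(), "snp"] == "snp1"

    def test_missing_genotypes_use_exact_subset_moments(self, community_matrix_100):
        rng = np.random.default_rng(15)
        n = 100
        g = simulate_genotypes(n, 0.3, rng).astype(int)
        g_miss = g.copy()
        g_miss[[3, 50]] = -1
        model = DistanceAssociation(community_matrix_100, use_grid=False)
        model.align_to(list(community_matrix_100.ids))
        rec = model.test_snp(g_miss)
        assert rec.n_eff == 98 and not rec.skipped
        # manual: drop the two subjects and recompute from scratch
        keep = np.ones(n, bool)
        keep[[3, 50]] = False
        sub = community_matrix_100.filter(
            [s for s, k in zip(community_matrix_100.ids, keep) if k])
        model2 = DistanceAssociation(sub, use_grid=False)
        model2.align_to(list(sub.ids))
        rec2 = model2.test_snp(g[keep])
        assert rec.z_m == pytest.approx(rec2.z_m, rel=1e-9)
        assert rec.p_adj_m == pytest.approx(rec2.p_adj_m, rel=1e-9)

    def test_skip_reasons_are_reported(self, community_matrix_100):
        model = DistanceAssociation(community_matrix_100)
        model.align_to(list(community_matrix_100.ids))
        assert model.test_snp(np.zeros(100, int)).skip_reason == "monomorphic"
        rare = np.zeros(100, int)
        rare[:2] = 1
        assert "maf<" in model.test_snp(rare).skip_reason

    def test_no_sample_overlap_is_fatal(self, community_matrix_100, tmp_path):
        rng = np.random.default_rng(16)
        G = np.vstack([simulate_genotypes(10, 0.3, rng)])
        prefix = str(tmp_path / "other")
        write_plink(prefix, G, sample_ids=[f"X{i}" for i in range(10)])
        with pytest.raises(ValueError, match="no overlapping samples"):
            DistanceAssociation(community_matrix_100).fit(prefix)


class TestQQLambda:
    def test_uniform_grid_gives_unit_lambda(self):
        p = (np.arange(1, 1001) - 0.5) / 1000
        exp, obs, lam = qq_lambda(p)
        assert lam == pytest.approx(1.0, abs=2e-3)
        np.testing.assert_allclose(exp, obs, atol=5e-3)

    def test_deflated_pvalues_inflate_lambda(self):
        p = (np.arange(1, 1001) - 0.5) / 1000
        assert qq_lambda(p * 0.1)[2] > 1.5

    def test_requires_enough_pvalues(self):
        with pytest.raises(ValueError, match="at least 100"):
            qq_lambda(np.full(50, 0.5))


class TestCli:
    def test_scan_subcommand_end_to_end(self, tmp_path, community_matrix_100):
        rng = np.random.default_rng(17)
        prefix, _ = build_panel(tmp_path, community_matrix_100, 120, rng)
        dpath = tmp_path / "d.tsv"
        write_distance_matrix(community_matrix_100, dpath)
        env = simulate_environment(100, rng)
        cov = pd.DataFrame(
            {"age": rng.normal(60, 8, 100), "exposure": env},
            index=list(community_matrix_100.ids))
        cpath = tmp_path / "c.tsv"
        cov.to_csv(cpath, sep="\t", index_label="sample")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "scan", "--distance", str(dpath), "--plink", prefix,
            "--covariates", str(cpath), "--covariate-columns", "age",
            "--env", "exposure", "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "out.assoc.tsv", sep="\t")
        assert {"z_m", "p_adj_m", "z_i", "p_adj_joint"} <= set(table.columns)
        assert len(table) > 100

    def test_user_error_exit_code(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "scan", "--distance", str(tmp_path / "absent.tsv"),
            "--plink", str(tmp_path / "nope")])
        assert res.exit_code == 1
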