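"""Generator moment checks, determinism, and truth-bundle round trips."""

import json

import numpy as np
import pytest

from methgwas import (
    compute_kinship,
    simulate_genotypes,
    simulate_insertion_counts,
    simulate_methylation_calls,
    simulate_phenotypes,
    write_fixture_bundle,
)
from methgwas.methylation import FeatureAnnotation
from methgwas.simulate import SimulationConfig, clinal_config, default_config


class TestConfigValidation:
    def test_rejects_more_clusters_than_lines(self):
        with pytest.raises(ValueError, match="n_clusters"):
            SimulationConfig(n_lines=5, n_clusters=10).validate()

    def test_rejects_duplicate_or_out_of_range_qtls(self):
        with pytest.raises(ValueError, match="unique"):
            SimulationConfig(qtl_spec=((1, 0, 0.1), (1, 0, 0.2))).validate()
        with pytest.raises(ValueError, match="range"):
            SimulationConfig(n_snps=10, qtl_spec=((10, 0, 0.1),)).validate()

    def test_rejects_bad_variance_fractions(self):
        with pytest.raises(ValueError):
            SimulationConfig(h2_background_1=1.2).validate()


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_lines=60, n_snps=200, seed=42)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.pos, b.pos)

    def test_divergence_free_limit(self):
        """fst -> 0: cluster allele frequencies collapse onto the ancestral p0."""
        cfg = SimulationConfig(n_lines=2000, n_snps=300, n_clusters=4, fst=1e-10, seed=5)
        g = simulate_genotypes(cfg)
        freqs = np.stack([g.values[g.clusters == c].mean(axis=0) for c in range(4)])
        # between-cluster variance should be pure binomial sampling noise
        between = freqs.var(axis=0, ddof=0).mean()
        n_per = 500
        sampling = (freqs.mean(axis=0) * (1 - freqs.mean(axis=0)) / n_per).mean()
        assert between < 3 * sampling

    def test_balding_nichols_between_cluster_variance(self):
        """E[var_c(p)] = fst * E[p0(1-p0)] with p0 ~ U(a, 1-a)."""
        fst, a = 0.3, 0.05
        cfg = SimulationConfig(
            n_lines=3000, n_snps=2000, n_clusters=2, fst=fst, maf_floor=a, seed=7
        )
        g = simulate_genotypes(cfg)
        f = np.stack([g.values[g.clusters == c].mean(axis=0) for c in range(2)])
        # unbiased between-cluster variance of the two true frequencies:
        # (f1-f2)^2/2 minus binomial sampling contribution
        n_per = 1500
        per_snp = (f[0] - f[1]) ** 2 / 2 - (f * (1 - f) / n_per).sum(axis=0) / 2
        b = 1 - a
        e_pq = 0.5 - (b**3 - a**3) / (3 * (b - a))  # E[p(1-p)] under U(a,b)
        expected = fst * e_pq
        sem = per_snp.std() / np.sqrt(per_snp.size)
        assert per_snp.mean() == pytest.approx(expected, abs=3 * sem)

    def test_cluster_freq_overrides_and_positions(self):
        cfg = SimulationConfig(n_lines=1000, n_snps=50, n_clusters=2, seed=1)
        cfg.cluster_freq_overrides = {3: (0.05, 0.95)}
        g = simulate_genotypes(cfg)
        f0 = g.values[g.clusters == 0, 3].mean()
        f1 = g.values[g.clusters == 1, 3].mean()
        assert f0 < 0.15 and f1 > 0.85
        assert len(np.unique(g.chrom)) == cfg.n_chromosomes
        # positions restart per chromosome and are increasing within
        for c in np.unique(g.chrom):
            p = g.pos[g.chrom == c]
            assert (np.diff(p) > 0).all()

    def test_missing_rate_masks_entries(self):
        cfg = SimulationConfig(n_lines=100, n_snps=100, missing_rate=0.1, seed=2)
        g = simulate_genotypes(cfg)
        frac = np.isnan(g.values).mean()
        assert 0.05 < frac < 0.15

    def test_ld_blocks_create_local_correlation(self):
        cfg = SimulationConfig(
            n_lines=400, n_snps=100, n_clusters=1, fst=0.0, ld_blocks=True, seed=3
        )
        g = simulate_genotypes(cfg)
        within = np.corrcoef(g.values[:, 1], g.values[:, 2])[0, 1]
        across = np.corrcoef(g.values[:, 5], g.values[:, 95])[0, 1]
        assert within > 0.7 and abs(across) < 0.3


class TestPhenotypes:
    def test_independent_noise_gives_uncorrelated_traits(self, rng):
        cfg = SimulationConfig(
            n_lines=800, n_snps=300, seed=9, shared_factor_sd=0.0, shared_structured_frac=0.0,
            h2_background_1=0.0, h2_background_2=0.0, noise_sd_1=1.0, noise_sd_2=1.0,
        )
        g = simulate_genotypes(cfg)
        K = compute_kinship(g)
        ph = simulate_phenotypes(g, K, cfg)
        # traits are shared-factor + noise; with loadings (1, 0) the shared
        # factor only enters trait1, so correlation is pure chance
        r = np.corrcoef(ph.table.trait1, ph.table.trait2)[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_lines)

    def test_trait_correlation_matches_analytic_target(self):
        """cor = s / sqrt((1+n1^2)(s^2+n2^2)) with an iid unit shared factor."""
        s, n1, n2 = 0.9, 0.223607, 0.593266
        cfg = SimulationConfig(
            n_lines=800, n_snps=400, seed=17, shared_factor_sd=s,
            shared_structured_frac=0.0, h2_background_1=0.0, h2_background_2=0.0,
            noise_sd_1=n1, noise_sd_2=n2,
        )
        g = simulate_genotypes(cfg)
        K = compute_kinship(g)
        expected = s / np.sqrt((1 + n1**2) * (s**2 + n2**2))
        rs = []
        for seed in range(5):
            cfg.seed = 17 + seed
            g = simulate_genotypes(cfg)
            ph = simulate_phenotypes(g, compute_kinship(g), cfg)
            rs.append(np.corrcoef(ph.table.trait1, ph.table.trait2)[0, 1])
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)

    def test_planted_qtl_recovered_by_ols(self):
        cfg = SimulationConfig(
            n_lines=800, n_snps=200, seed=23, qtl_spec=((10, 0.0, 0.5),),
            shared_factor_sd=0.0, shared_structured_frac=0.0,
            h2_background_1=0.0, h2_background_2=0.0, noise_sd_1=1.0, noise_sd_2=1.0,
        )
        g = simulate_genotypes(cfg)
        ph = simulate_phenotypes(g, compute_kinship(g), cfg)
        x = g.values[:, 10]
        xz = (x - x.mean()) / x.std()
        y = ph.table.trait2.to_numpy()
        beta = (xz @ (y - y.mean())) / (xz @ xz)
        se = np.sqrt(y.var() / (xz @ xz))
        assert abs(beta - 0.5) < 2 * se

    def test_dimension_mismatch_errors(self, small_panel):
        cfg, geno, K = small_panel
        other = SimulationConfig(n_lines=10, n_snps=20, n_clusters=2, seed=0)
        g2 = simulate_genotypes(other)
        with pytest.raises(ValueError, match="dimension"):
            simulate_phenotypes(g2, K, other)


class TestInsertionCounts:
    def _geno(self, n=2000, seed=0):
        cfg = SimulationConfig(n_lines=n, n_snps=10, n_clusters=1, fst=0.0, seed=seed)
        return cfg, simulate_genotypes(cfg)

    def test_no_interaction_means_equal(self):
        cfg, g = self._geno()
        cfg.insertion_interaction_log_ratio = 0.0
        cfg.insertion_baseline = 1.0
        counts = simulate_insertion_counts(g, 0, [1, 2, 3], cfg)
        boosted = (g.values[:, 0] == 1) & (g.values[:, [1, 2, 3]].sum(axis=1) >= 2)
        se = np.sqrt(counts.var() * (1 / boosted.sum() + 1 / (~boosted).sum()))
        assert abs(counts[boosted].mean() - counts[~boosted].mean()) < 3 * se

    def test_thirty_fold_ratio_recovered(self):
        cfg, g = self._geno(n=4000, seed=4)
        cfg.insertion_baseline = 0.1
        cfg.insertion_interaction_log_ratio = np.log(30.0)
        counts = simulate_insertion_counts(g, 0, [1, 2, 3], cfg)
        boosted = (g.values[:, 0] == 1) & (g.values[:, [1, 2, 3]].sum(axis=1) >= 2)
        ratio = counts[boosted].mean() / counts[~boosted].mean()
        # NB sampling error on both class means; generous 3-sigma band
        assert 20 < ratio < 45

    def test_deterministic_and_index_checked(self):
        cfg, g = self._geno(n=200, seed=5)
        a = simulate_insertion_counts(g, 0, [1, 2], cfg)
        b = simulate_insertion_counts(g, 0, [1, 2], cfg)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="out of range"):
            simulate_insertion_counts(g, 99, [1], cfg)


class TestMethylationCalls:
    FEATS = [FeatureAnnotation(f"TE{i}", "Chr1", i * 1000, i * 1000 + 600) for i in range(5)]

    def test_zero_level_gives_zero_counts(self):
        calls = simulate_methylation_calls(self.FEATS, [0.0] * 5, depth=30, seed=1)
        assert (calls["mc"] == 0).all()

    def test_level_recovered_at_depth(self):
        feats = [FeatureAnnotation("big", "Chr1", 0, 5000)]
        calls = simulate_methylation_calls(feats, [0.375], depth=50, seed=2, sites_per_feature=200)
        est = calls["mc"].sum() / calls["total"].sum()
        assert est == pytest.approx(0.375, abs=0.02)

    def test_zero_coverage_sites_emitted(self):
        calls = simulate_methylation_calls(self.FEATS, [0.5] * 5, depth=0.5, seed=3)
        assert (calls["total"] == 0).any()
        assert ((calls["mc"] <= calls["total"])).all()

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            simulate_methylation_calls(self.FEATS, [0.5] * 5, depth=-1)


class TestFixtureBundle:
    def test_bundle_truth_and_determinism(self, tmp_path):
        cfg = clinal_config(seed=6, n_lines=80, n_snps=400, n_chromosomes=2)
        paths = write_fixture_bundle(cfg, tmp_path / "a")
        truth = json.loads((tmp_path / "a" / "truth.json").read_text())
        planted = {j for j, _, _ in cfg.qtl_spec}
        assert planted == {q[0] for q in truth["qtl_spec"]}
        assert truth["partner_snp"] is not None
        paths2 = write_fixture_bundle(cfg, tmp_path / "b")
        for key in paths:
            a = (tmp_path / "a" / paths[key].split("/")[-1]).read_bytes()
            b = (tmp_path / "b" / paths2[key].split("/")[-1]).read_bytes()
            assert a == b, f"{key} not byte-identical under the same seed"

    def test_default_config_places_qtl(self):
        cfg = default_config(seed=0)
        (j, e1, e2), = cfg.qtl_spec
        assert e1 == 0.0 and e2 > 0
        assert j in cfg.cluster_freq_overrides
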