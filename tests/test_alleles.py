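"""Cumulative-allele modelling and frequency-matched permutation tests."""

import numpy as np
import pandas as pd
import pytest

from methgwas import GenotypeMatrix, compute_kinship, simulate_genotypes
from methgwas.alleles import (
    FocalAlleleSet,
    PermutationSpec,
    additive_fit,
    clinal_test,
    cumulative_counts,
    epistasis_insertion_test,
    ld_with_focal_test,
    matched_snp_sample,
    orient_alleles,
    variance_explained_r2,
)
from methgwas.simulate import SimulationConfig
from oracles import matched_perm_exhaustive_p


def _geno(values):
    values = np.asarray(values, float)
    m = values.shape[1]
    return GenotypeMatrix(values=values, chrom=np.array(["Chr1"] * m), pos=np.arange(1, m + 1) * 100)


def _scan_table(betas):
    return pd.DataFrame(
        {"snp_index": np.arange(len(betas)), "beta": betas, "p_value": 0.5}
    )


class TestOrientation:
    def test_sign_convention_and_flip(self):
        fs = orient_alleles(_scan_table([-0.3, 0.3]), [0, 1])
        assert list(fs.decreasing_code) == [1, 0]
        flipped = orient_alleles(_scan_table([0.3, -0.3]), [0, 1])
        assert list(flipped.decreasing_code) == [0, 1]

    def test_zero_beta_cannot_orient(self):
        with pytest.raises(ValueError, match="orient"):
            orient_alleles(_scan_table([0.0]), [0])

    def test_untested_snp_raises(self):
        with pytest.raises(KeyError):
            orient_alleles(_scan_table([-0.3]), [5])


class TestCounts:
    def test_hand_tally(self):
        g = _geno([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 0, 1, 0, 0]])
        fs = FocalAlleleSet(np.arange(5), np.array([1, 1, 1, 0, 0]))
        # line2 carries decreasing alleles at snp0 (1), snp2 (1), snp3 (0), snp4 (0)
        assert list(cumulative_counts(g, fs)) == [3.0, 2.0, 4.0]
        all_dec = FocalAlleleSet(np.arange(5), np.ones(5, int))
        assert cumulative_counts(g, all_dec)[0] == 5.0
        assert cumulative_counts(g, all_dec)[1] == 0.0

    def test_missing_focal_genotype_propagates(self):
        g = _geno([[1, np.nan], [1, 0]])
        fs = FocalAlleleSet(np.array([0, 1]), np.array([1, 1]))
        c = cumulative_counts(g, fs)
        assert np.isnan(c[0]) and c[1] == 1.0


class TestAdditiveFitAndR2:
    def test_slope_recovery_and_covariance_identity(self, rng):
        counts = rng.integers(0, 6, 600).astype(float)
        y = -0.2 * counts + 0.3 * rng.standard_normal(600)
        fit = additive_fit(y, counts)
        se = 0.3 / (np.sqrt(600) * counts.std())
        assert fit["slope"] == pytest.approx(-0.2, abs=2 * se)
        # algebraic identity: slope * var(count) = cov(y, count)
        cov = np.cov(y, counts, ddof=0)[0, 1]
        assert fit["slope"] * counts.var() == pytest.approx(cov)
        assert fit["class_means"]["n"].sum() == 600

    def test_constant_y_zero_slope_single_class_errors(self):
        counts = np.array([0.0, 1, 2, 1])
        assert additive_fit(np.ones(4), counts)["slope"] == pytest.approx(0.0)
        with pytest.raises(ValueError, match="classes"):
            additive_fit(np.ones(4), np.ones(4))

    def test_r2_identities(self, rng):
        n = 400
        G = (rng.random((n, 5)) < 0.4).astype(float)
        g = _geno(G)
        y_lin = G @ np.array([1.0, -2, 0.5, 1, 1]) + 3
        assert variance_explained_r2(y_lin, g, range(5)) == pytest.approx(1.0)
        y = rng.standard_normal(n)
        r2_single = variance_explained_r2(y, g, [0])
        assert r2_single == pytest.approx(np.corrcoef(y, G[:, 0])[0, 1] ** 2)

    def test_r2_null_expectation(self, rng):
        n, k = 800, 5
        vals = []
        G = (rng.random((n, k)) < 0.5).astype(float)
        g = _geno(G)
        for _ in range(40):
            vals.append(variance_explained_r2(rng.standard_normal(n), g, range(k)))
        # E[R^2] = k/(n-1) under the null
        assert np.mean(vals) == pytest.approx(k / (n - 1), abs=3 * np.std(vals) / np.sqrt(40))

    def test_r2_guards(self, rng):
        G = (rng.random((4, 5)) < 0.5).astype(float)
        with pytest.raises(ValueError, match="n >"):
            variance_explained_r2(rng.standard_normal(4), _geno(G), range(5))


class TestMatchedSampling:
    def test_exact_mac_matching_by_construction(self):
        cfg = SimulationConfig(n_lines=100, n_snps=400, n_clusters=2, fst=0.1, seed=31)
        g = simulate_genotypes(cfg)
        fs = FocalAlleleSet(np.array([10, 20]), np.array([1, 1]))
        spec = PermutationSpec(n_perm=50, seed=3)
        sets = matched_snp_sample(g, fs, spec)
        mac, maf = g.allele_counts()
        assert sets.shape == (50, 2)
        assert (mac[sets[:, 0]] == mac[10]).all() and (mac[sets[:, 1]] == mac[20]).all()
        assert (sets[:, 0] != 10).all() and (sets[:, 1] != 20).all()
        binspec = PermutationSpec(n_perm=50, mode="frequency-bin", bin_half_width=0.01, seed=3)
        bsets = matched_snp_sample(g, fs, binspec)
        assert (np.abs(maf[bsets[:, 0]] - maf[10]) <= 0.01).all()

    def test_unique_candidate_gives_identical_replicates(self):
        # construct genotypes where exactly one SNP shares the focal MAC
        rows = np.zeros((10, 4))
        rows[:3, 0] = 1  # focal: MAC 3
        rows[:3, 1] = 1  # the only match
        rows[:5, 2] = 1
        rows[:1, 3] = 1
        g = _geno(rows)
        fs = FocalAlleleSet(np.array([0]), np.array([1]))
        sets = matched_snp_sample(g, fs, PermutationSpec(n_perm=20, seed=1))
        assert (sets == 1).all()

    def test_no_match_error_names_snp(self):
        rows = np.zeros((10, 2))
        rows[:3, 0] = 1
        rows[:5, 1] = 1
        g = _geno(rows)
        fs = FocalAlleleSet(np.array([0]), np.array([1]))
        with pytest.raises(ValueError, match="focal index 0"):
            matched_snp_sample(g, fs, PermutationSpec(n_perm=5, seed=1))

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_lines=80, n_snps=200, seed=33)
        g = simulate_genotypes(cfg)
        fs = FocalAlleleSet(np.array([5]), np.array([1]))
        a = matched_snp_sample(g, fs, PermutationSpec(n_perm=30, seed=7))
        b = matched_snp_sample(g, fs, PermutationSpec(n_perm=30, seed=7))
        assert np.array_equal(a, b)


class TestPermutationTests:
    def test_clinal_constant_longitude_errors(self):
        cfg = SimulationConfig(n_lines=60, n_snps=100, seed=35)
        g = simulate_genotypes(cfg)
        fs = FocalAlleleSet(np.array([3]), np.array([1]))
        with pytest.raises(ValueError, match="constant"):
            clinal_test(g, fs, np.ones(60), PermutationSpec(n_perm=10, seed=1))

    def test_partner_among_focal_is_extreme(self):
        cfg = SimulationConfig(n_lines=200, n_snps=300, n_clusters=1, fst=0.0, seed=37)
        g = simulate_genotypes(cfg)
        fs = FocalAlleleSet(np.array([5, 10, 15]), np.array([1, 1, 1]))
        spec = PermutationSpec(n_perm=200, seed=2)
        res = ld_with_focal_test(g, fs, partner_snp=5, spec=spec)
        assert res["p_value"] <= 5 / 201  # self-correlation sits in the far tail

    def test_pvalue_range_and_determinism(self):
        cfg = SimulationConfig(n_lines=100, n_snps=200, seed=39)
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        lon = rng.uniform(0, 30, 100)
        fs = FocalAlleleSet(np.array([2, 4]), np.array([1, 0]))
        spec = PermutationSpec(n_perm=99, seed=11)
        r1 = clinal_test(g, fs, lon, spec)
        r2 = clinal_test(g, fs, lon, spec)
        assert r1["p_value"] == r2["p_value"]
        assert 1 / 100 <= r1["p_value"] <= 1.0

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        """<= 12 candidates per focal locus: the permutation p matches the
        exact enumeration over all candidate combinations."""
        rng = np.random.default_rng(41)
        n = 40
        # focal SNPs with MAC 8 and MAC 12; 6 and 4 candidates respectively
        cols = []
        for mac, count in ((8, 1 + 6), (12, 1 + 4), (15, 5)):
            for _ in range(count):
                col = np.zeros(n)
                col[rng.choice(n, mac, replace=False)] = 1
                cols.append(col)
        g = _geno(np.column_stack(cols))
        mac, _ = g.allele_counts()
        focal = FocalAlleleSet(np.array([0, 7]), np.array([1, 1]))
        lon = rng.uniform(0, 30, n)
        R = 50_000
        res = clinal_test(g, focal, lon, PermutationSpec(n_perm=R, seed=5))
        cand0 = [j for j in np.where(mac == mac[0])[0] if j != 0]
        cand1 = [j for j in np.where(mac == mac[7])[0] if j != 7]
        assert len(cand0) == 6 and len(cand1) == 4

        def reaches(combo):
            counts = g.values[:, list(combo)].sum(axis=1)
            r = np.corrcoef(counts, lon)[0, 1]
            return abs(r) >= abs(res["r_obs"])

        p_exact, q = matched_perm_exhaustive_p(reaches, [cand0, cand1], R)
        se = np.sqrt(max(q * (1 - q), 1e-6) / R)
        assert abs(res["p_value"] - p_exact) <= 3 * se + 2 / (R + 1)


class TestEpistasisTest:
    def _fixture(self, seed=43):
        cfg = SimulationConfig(n_lines=300, n_snps=300, n_clusters=1, fst=0.0, seed=seed)
        g = simulate_genotypes(cfg)
        fs = FocalAlleleSet(np.arange(5), np.ones(5, int))
        return g, fs

    def test_all_zero_insertions_give_p_one(self):
        g, fs = self._fixture()
        res = epistasis_insertion_test(
            np.zeros(300), g, partner_snp=10, focal=fs, spec=PermutationSpec(n_perm=50, seed=1)
        )
        nonempty = res.dropna(subset=["obs_mean"])
        assert (nonempty["p_value"] == 1.0).all()

    def test_empty_class_flagged_not_zero_filled(self):
        g, fs = self._fixture()
        res = epistasis_insertion_test(
            np.ones(300), g, 10, fs, PermutationSpec(n_perm=20, seed=1), k_grid=[0, 99]
        )
        row = res.set_index("k").loc[99]
        assert row["n"] == 0 and np.isnan(row["obs_mean"]) and np.isnan(row["p_value"])

    def test_monomorphic_partner_errors(self):
        g, fs = self._fixture()
        g.values[:, 10] = 1.0
        with pytest.raises(ValueError, match="monomorphic"):
            epistasis_insertion_test(
                np.ones(300), g, 10, fs, PermutationSpec(n_perm=20, seed=1)
            )

    def test_null_calibration_on_unstructured_panel(self):
        """No planted interaction: one-sided class p-values are roughly
        uniform (pooled over classes and replicates).  Frequency-bin
        matching on a panel large enough that each locus has many
        candidates; exact-MAC matching on a tiny panel gives an atomically
        discrete (hence non-uniform) null."""
        rng = np.random.default_rng(47)
        ps = []
        for rep in range(6):
            cfg = SimulationConfig(n_lines=300, n_snps=2000, n_clusters=1, fst=0.0, seed=100 + rep)
            g = simulate_genotypes(cfg)
            fs = FocalAlleleSet(np.arange(5), np.ones(5, int))
            ins = rng.poisson(1.0, 300).astype(float)
            spec = PermutationSpec(n_perm=200, mode="frequency-bin", bin_half_width=0.02, seed=rep)
            res = epistasis_insertion_test(ins, g, 10, fs, spec, k_grid=range(0, 4))
            ps.extend(res["p_value"].dropna().tolist())
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.2
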