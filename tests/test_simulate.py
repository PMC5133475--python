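"""Generative properties of the synthetic family data."""

import numpy as np
import pytest
from scipy import stats

import famassoc as fa


class TestPedigree:
    def test_smallest_pedigree(self):
        cfg = fa.SimConfig(n_families=1, family_size_mean=4,
                           n_generations=2, seed=5)
        ped = fa.simulate_pedigree(cfg)
        founders = set(ped.founders())
        kids = [r for r in ped.rows.itertuples(index=False)
                if r.father_id is not None]
        assert len(founders) == 2
        for k in kids:
            assert (str(k.family_id), str(k.father_id)) in founders
            assert (str(k.family_id), str(k.mother_id)) in founders

    def test_family_count_and_size(self):
        cfg = fa.SimConfig(seed=7)  # defaults: 20 families of ~48
        ped = fa.simulate_pedigree(cfg)
        fams = ped.rows.family_id.unique()
        assert len(fams) == 20
        total = len(ped.rows)
        # Poisson offspring counts: expect within ~15% of 20 * 48
        assert 0.8 * 960 < total < 1.2 * 960

    def test_acyclic_and_parents_present(self):
        # Pedigree.__init__ validates acyclicity and in-family parents
        cfg = fa.SimConfig(n_families=3, family_size_mean=30, seed=13)
        ped = fa.simulate_pedigree(cfg)
        nonf = ped.rows.father_id.notna().sum()
        assert nonf > 0


class TestGeneDrop:
    def test_founder_allele_frequency(self):
        # one-SNP blocks, maf pinned at 0.3: founder frequency binomial
        cfg = fa.SimConfig(n_families=10, family_size_mean=10, n_snps=1,
                           block_size=1, maf_range=(0.3, 0.3), seed=23)
        ped = fa.simulate_pedigree(cfg)
        geno = fa.gene_drop(ped, cfg)
        f_rows = [i for i, key in enumerate(geno.individuals)
                  if key in set(ped.founders())]
        d = geno.dosage[f_rows, 0]
        freq = d.mean() / 2.0
        n_alleles = 2 * len(f_rows)
        sd = np.sqrt(0.3 * 0.7 / n_alleles)
        assert abs(freq - 0.3) < 3 * sd

    def test_zero_block_correlation(self):
        cfg = fa.SimConfig(n_families=12, family_size_mean=12, n_snps=10,
                           block_size=5, within_block_r=0.0,
                           maf_range=(0.3, 0.5), seed=29)
        ped = fa.simulate_pedigree(cfg)
        geno = fa.gene_drop(ped, cfg)
        f_rows = [i for i, key in enumerate(geno.individuals)
                  if key in set(ped.founders())]
        D = geno.dosage[f_rows]
        r = np.corrcoef(D.T)
        off = r[np.triu_indices(10, 1)]
        assert abs(off.mean()) < 3.0 / np.sqrt(len(f_rows))

    def test_block_ld_present(self):
        cfg = fa.SimConfig(n_families=20, family_size_mean=20, n_snps=10,
                           block_size=5, within_block_r=0.9,
                           maf_range=(0.2, 0.4), seed=31)
        ped = fa.simulate_pedigree(cfg)
        geno = fa.gene_drop(ped, cfg)
        f_rows = [i for i, key in enumerate(geno.individuals)
                  if key in set(ped.founders())]
        r = np.corrcoef(geno.dosage[f_rows].T)
        within = np.mean([r[i, i + 1] for i in (0, 1, 2, 3, 5, 6, 7, 8)])
        across = abs(r[4, 5])
        assert within > 0.4  # thresholded AR(1) keeps strong adjacent LD
        assert across < 0.3  # blocks recombine freely

    def test_parent_offspring_dosage_covariance(self):
        """cov(parent, child dosage) = 2 maf (1-maf) * Phi with Phi=1/4."""
        maf = 0.3
        covs = []
        for seed in range(30):
            cfg = fa.SimConfig(n_families=6, family_size_mean=15, n_snps=1,
                               block_size=1, maf_range=(maf, maf), seed=seed)
            ped = fa.simulate_pedigree(cfg)
            geno = fa.gene_drop(ped, cfg)
            idx = {k: i for i, k in enumerate(geno.individuals)}
            for r in ped.rows.itertuples(index=False):
                if r.father_id is None:
                    continue
                i = idx[(str(r.family_id), str(r.individual_id))]
                j = idx[(str(r.family_id), str(r.father_id))]
                covs.append((geno.dosage[i, 0], geno.dosage[j, 0]))
        pairs = np.array(covs)
        emp = np.cov(pairs.T)[0, 1]
        expected = 2.0 * maf * (1 - maf) * 0.5  # 2 phi(1-phi)... = 0.21
        assert abs(emp - expected) < 0.05

    def test_hardy_weinberg_among_founders(self):
        cfg = fa.SimConfig(n_families=40, family_size_mean=6,
                           n_generations=2, n_snps=20, block_size=4,
                           maf_range=(0.2, 0.5), seed=37)
        ped = fa.simulate_pedigree(cfg)
        geno = fa.gene_drop(ped, cfg)
        f_rows = [i for i, key in enumerate(geno.individuals)
                  if key in set(ped.founders())]
        D = geno.dosage[f_rows]
        n = len(f_rows)
        failures = 0
        for j in range(20):
            counts = np.array([(D[:, j] == k).sum() for k in (0, 1, 2)])
            p = D[:, j].mean() / 2.0
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            chi2 = ((counts - exp) ** 2 / exp).sum()
            if stats.chi2.sf(chi2, 1) < 0.001:
                failures += 1
        assert failures <= 1  # expected failure rate <= nominal alpha


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = fa.SimConfig(n_families=2, family_size_mean=10, n_snps=8, seed=41)
        g1 = fa.gene_drop(fa.simulate_pedigree(cfg), cfg)
        g2 = fa.gene_drop(fa.simulate_pedigree(cfg), cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_different_seed_differs(self):
        c1 = fa.SimConfig(n_families=2, family_size_mean=10, n_snps=8, seed=41)
        c2 = fa.SimConfig(n_families=2, family_size_mean=10, n_snps=8, seed=42)
        g1 = fa.gene_drop(fa.simulate_pedigree(c1), c1)
        g2 = fa.gene_drop(fa.simulate_pedigree(c2), c2)
        assert g1.dosage.shape != g2.dosage.shape or \
            not np.array_equal(g1.dosage, g2.dosage)


class TestPhenotypes:
    def test_unknown_causal_snp_rejected(self, small_cfg, small_data):
        ped, geno = small_data
        with pytest.raises(KeyError):
            fa.simulate_longitudinal_phenotypes(
                geno, ped, small_cfg, [("nope", 1.0)])

    def test_null_trait_is_noise(self, small_data):
        ped, geno = small_data
        cfg = fa.SimConfig(n_families=4, family_size_mean=20, n_snps=40,
                           block_size=8, trait_heritability=0.0,
                           covariate_effects=(0.0, 0.0, 0.0), seed=11)
        pheno = fa.simulate_longitudinal_phenotypes(geno, ped, cfg)
        trait = fa.adjust_and_average(pheno, "DBP")
        # no dosage should predict the trait strongly
        y = trait.values
        order = list(trait.values.index)
        rows = [geno.individuals.index(k) for k in order]
        rs = [abs(np.corrcoef(geno.dosage[rows, j], y)[0, 1])
              for j in range(10)]
        assert max(rs) < 4.0 / np.sqrt(len(y))

    def test_noise_free_causal_limit(self, small_data):
        ped, geno = small_data
        cfg = fa.SimConfig(n_families=4, family_size_mean=20, n_snps=40,
                           block_size=8, trait_heritability=0.0,
                           residual_sd=1e-6, exam_missing_rate=0.0, seed=11)
        pheno = fa.simulate_longitudinal_phenotypes(
            geno, ped, cfg, [("snp7", 5.0)])
        trait = fa.adjust_and_average(pheno, "DBP")
        rows = [geno.individuals.index(k) for k in trait.values.index]
        d = geno.dosage[rows, geno.snp_index("snp7")]
        # adjust the dosage for the same covariates the trait was adjusted for
        cov = pheno.rows.groupby(["family_id", "individual_id"]).agg(
            age=("age", "mean"), smoking=("smoking", "mean"),
            medication=("medication", "mean")).loc[trait.values.index]
        X = np.column_stack([np.ones(len(d)), cov.to_numpy(dtype=float)])
        d_adj = d - X @ np.linalg.lstsq(X, d, rcond=None)[0]
        r = np.corrcoef(d_adj, trait.values)[0, 1]
        assert abs(r) > 0.99

    def test_htn_and_pressure_invariants(self, small_cfg, small_data):
        ped, geno = small_data
        pheno = fa.simulate_longitudinal_phenotypes(geno, ped, small_cfg)
        rows = pheno.rows
        assert (rows.SBP > rows.DBP).all()
        med = rows.medication == 1
        assert (rows.loc[med, "HTN"] == 1).all()


class TestExpression:
    def test_missing_pair_rejected(self, small_cfg, small_data):
        ped, geno = small_data
        with pytest.raises(KeyError):
            fa.simulate_expression(geno, ped, small_cfg, ("snp1", "nope"))

    def test_strong_interaction_detected(self, small_data, small_K):
        ped, geno = small_data
        cfg = fa.SimConfig(n_families=4, family_size_mean=20, n_snps=40,
                           block_size=8, interaction_effect=3.0,
                           trait_heritability=0.0, seed=11)
        expr = fa.simulate_expression(geno, ped, cfg, ("snp1", "snp30"),
                                      expr_residual_sd=0.05)
        res = fa.interaction_test(expr, geno.dosage_of("snp1"),
                                  geno.dosage_of("snp30"), small_K)
        assert res.p < 1e-6
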