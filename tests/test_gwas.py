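"""QC, GRM, REML and marker-test behaviour of the mixed-model GWAS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import plain_null_model, unit_phenotypes
from gestarch.data import GRM, AssociationColumns as C, GenotypeMatrix, PhenotypeTable
from gestarch.gwas import (
    association_scan,
    bonferroni_threshold,
    compute_grm,
    fit_null_model,
    hwe_test,
    maf_by_cohort,
    reliability_to_weight,
    single_marker_test,
    variant_qc,
)
from gestarch.simulate import SimConfig, simulate_genotypes, simulate_trait


def _matrix(dosages, positions=None, chrom="1"):
    d = np.asarray(dosages)
    m = d.shape[1]
    pos = positions if positions is not None else np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        dosages=d,
        variants=pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(m)],
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
            }
        ),
        individuals=np.array([f"i{k}" for k in range(d.shape[0])]),
    )


class TestHWE:
    @pytest.mark.parametrize(
        "counts,expected_p",
        [
            ((25, 50, 25), 1.0),  # perfect proportions, chi-square 0
            ((30, 40, 30), 0.0455),  # chi-square = 4.0
        ],
    )
    def test_known_tables(self, counts, expected_p):
        assert hwe_test(*counts) == pytest.approx(expected_p, abs=2e-4)

    def test_total_heterozygote_deficit_fails_filter(self):
        assert hwe_test(50, 0, 50) < 1e-6

    def test_monomorphic_defined_as_one(self):
        assert hwe_test(100, 0, 0) == 1.0


class TestQC:
    def test_maf_and_hwe_rule(self):
        rng = np.random.default_rng(0)
        n = 2000
        mafs = [0.005, 0.02, 0.3, 0.5, 0.009]
        cols = []
        for p in mafs:
            g = rng.binomial(1, p, (n, 2)).sum(axis=1)  # HWE by construction
            cols.append(g)
        geno = _matrix(np.array(cols).T)
        kept, log = variant_qc(geno)
        # sampling can push a borderline frequency across 0.01; check the rule, not the draw
        expect = (log["maf"] > 0.01) & (log["hwe_p"] > 1e-6)
        assert (log["kept"] == expect).all()
        assert kept.n_variants == int(expect.sum()) == 3

    def test_idempotent(self, small_genotypes):
        once, _ = variant_qc(small_genotypes)
        twice, _ = variant_qc(once)
        assert np.array_equal(once.dosages, twice.dosages)


class TestGRM:
    def test_single_variant_hand_value(self):
        geno = _matrix(np.array([[0], [2]]))
        g = compute_grm(geno, maf_min=0.0)
        np.testing.assert_allclose(g.matrix, [[2, -2], [-2, 2]], atol=1e-12)

    def test_identical_individuals_equal_rows(self, small_genotypes):
        d = np.vstack([small_genotypes.dosages[:5], small_genotypes.dosages[:1]])
        geno = GenotypeMatrix(
            d, small_genotypes.variants, np.array([f"x{k}" for k in range(6)])
        )
        g = compute_grm(geno)
        assert g.matrix[5, 0] == pytest.approx(g.matrix[0, 0])

    def test_symmetry(self, fitted_gwas):
        grm = fitted_gwas[3]
        np.testing.assert_array_equal(grm.matrix, grm.matrix.T)

    def test_half_sib_structure(self):
        # two sire families: within-family relationship exceeds between
        rng = np.random.default_rng(5)
        m = 2000
        p = rng.uniform(0.1, 0.5, m)
        sires = rng.binomial(1, p, (2, 2, m))  # two sires x two haplotypes
        kids = []
        fam = []
        for f in range(2):
            for _ in range(20):
                paternal = sires[f, rng.integers(0, 2, m), np.arange(m)]
                maternal = rng.binomial(1, p)
                kids.append(paternal + maternal)
                fam.append(f)
        geno = _matrix(np.array(kids))
        G = compute_grm(geno).matrix
        fam = np.array(fam)
        off = ~np.eye(len(fam), dtype=bool)
        within = G[(fam[:, None] == fam[None, :]) & off].mean()
        between = G[fam[:, None] != fam[None, :]].mean()
        assert within > between


class TestReliabilityWeight:
    @pytest.mark.parametrize(
        "r2,expected",
        [(0.5, 1.0), (0.97, 0.030927835), (1.0, 1.0000010000e-06)],
    )
    def test_formula(self, r2, expected):
        assert reliability_to_weight(r2) == pytest.approx(expected, rel=1e-5)

    def test_domain(self):
        with pytest.raises(ValueError):
            reliability_to_weight(0.0)
        with pytest.raises(ValueError):
            reliability_to_weight(1.2)


class TestNullModel:
    def test_reml_matches_bruteforce_oracle(self):
        # independent oracle: direct -2 REML log-likelihood on the raw scale,
        # maximised on a dense grid, without whitening or eigendecomposition
        rng = np.random.default_rng(3)
        cfg = SimConfig(n_individuals=120, n_variants=400, seed=31)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_trait(geno, h2=0.5, n_causal=100, seed=32)
        grm = compute_grm(geno)
        null = fit_null_model(pheno, grm)

        R = np.diag(reliability_to_weight(pheno.reliability))
        X = np.ones((len(pheno), 1))
        y = pheno.y

        def neg2_reml(s2g, s2e):
            V = s2g * grm.matrix + s2e * R
            sign, logdet = np.linalg.slogdet(V)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            return logdet + np.linalg.slogdet(XtViX)[1] + float(r @ Vi @ r)

        ratios = np.linspace(0.05, 0.95, 46)
        best = min(
            (
                (neg2_reml(h * s, (1 - h) * s), h * s, (1 - h) * s)
                for h in ratios
                for s in np.linspace(0.3, 3.0, 28)
            ),
        )
        h2_oracle = best[1] / (best[1] + best[2])
        assert null.h2_ratio == pytest.approx(h2_oracle, abs=0.05)

    def test_null_h2_estimated_near_zero(self):
        cfg = SimConfig(n_individuals=1000, n_variants=1000, seed=41)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_trait(geno, h2=0.0, n_causal=10, seed=42)
        null = fit_null_model(pheno, compute_grm(geno))
        assert null.h2_ratio < 0.05

    def test_deterministic(self, fitted_gwas):
        _, pheno, _, grm, null, _ = fitted_gwas
        again = fit_null_model(pheno, grm)
        assert again.sigma2_g == null.sigma2_g and again.sigma2_e == null.sigma2_e


class TestMarkerTest:
    def test_reduces_to_simple_regression(self):
        ids = np.array(["a", "b", "c"])
        y = np.array([1.0, 2.0, 3.0])
        x = np.array([0.0, 1.0, 2.0])
        b, se, p = single_marker_test(
            unit_phenotypes(y, ids), x, plain_null_model(y, ids)
        )
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_matches_ols_with_identity_covariance(self):
        rng = np.random.default_rng(9)
        n = 200
        ids = np.array([f"i{k}" for k in range(n)])
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * x + rng.standard_normal(n)
        b, se, p = single_marker_test(
            unit_phenotypes(y, ids), x, plain_null_model(y, ids)
        )
        ols = stats.linregress(x, y)
        assert b == pytest.approx(ols.slope, rel=1e-8)

    def test_relabeling_invariance(self, fitted_gwas):
        geno, pheno, _, grm, null, _ = fitted_gwas
        x = geno.dosages[:, 10].astype(float)
        b0, se0, p0 = single_marker_test(pheno, x, null)
        perm = np.random.default_rng(1).permutation(len(pheno))
        pheno_p = PhenotypeTable(
            pheno.individual_id[perm], pheno.y[perm], pheno.reliability[perm]
        )
        grm_p = GRM(grm.matrix[np.ix_(perm, perm)], grm.ids[perm])
        null_p = fit_null_model(pheno_p, grm_p)
        b1, se1, p1 = single_marker_test(pheno_p, x[perm], null_p)
        assert (b1, se1, p1) == pytest.approx((b0, se0, p0), rel=1e-6)

    def test_zero_variance_marker_raises(self, fitted_gwas):
        _, pheno, _, _, null, _ = fitted_gwas
        with pytest.raises(ZeroDivisionError):
            single_marker_test(pheno, np.ones(len(pheno)), null)

    def test_known_effect_recovered_in_simulation(self):
        rng = np.random.default_rng(77)
        n, b_true = 2000, 0.25
        ids = np.array([f"i{k}" for k in range(n)])
        ests = []
        for _ in range(20):
            x = rng.binomial(2, 0.3, n).astype(float)
            y = b_true * x + rng.standard_normal(n)
            b, _, _ = single_marker_test(
                unit_phenotypes(y, ids), x, plain_null_model(y, ids)
            )
            ests.append(b)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - b_true) < 2 * mc_se + 1e-3

    def test_scan_agrees_with_single_tests(self, fitted_gwas):
        geno, pheno, _, _, null, assoc = fitted_gwas
        for j in (0, 50, 500):
            b, se, p = single_marker_test(pheno, geno.dosages[:, j].astype(float), null)
            assert assoc[C.BETA].iloc[j] == pytest.approx(b, rel=1e-10)
            assert assoc[C.P].iloc[j] == pytest.approx(p, rel=1e-8)

    def test_null_pvalues_calibrated(self):
        # h2 = 0 trait: fraction of P < 0.05 near nominal over >= 2000 variants
        cfg = SimConfig(n_individuals=500, n_variants=2500, seed=51)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_trait(geno, h2=0.0, n_causal=1, seed=52)
        geno_qc, _ = variant_qc(geno)
        null = fit_null_model(pheno, compute_grm(geno_qc))
        assoc = association_scan(geno_qc, pheno, null)
        rate = (assoc[C.P] < 0.05).mean()
        ci = 2 * np.sqrt(0.05 * 0.95 / len(assoc))
        # adjacent variants are LD-correlated; widen the binomial band accordingly
        assert abs(rate - 0.05) < 4 * ci + 0.01


class TestThresholdAndCohorts:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(100) == pytest.approx(5e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_maf_trajectory_recovered(self, small_genotypes):
        years = np.repeat([2000, 2005, 2010, 2015], 100)
        vid = small_genotypes.variants["id"].iloc[3]
        table = maf_by_cohort(small_genotypes, vid, years)
        dose = small_genotypes.dosage_of(vid)
        overall = dose.mean() / 2
        for _, row in table.iterrows():
            sel = years == row["cohort"]
            expect = dose[sel].mean() / 2
            if overall > 0.5:
                expect = 1 - expect
            assert row["maf"] == pytest.approx(expect)

    def test_single_cohort_is_overall_maf(self, small_genotypes):
        vid = small_genotypes.variants["id"].iloc[0]
        table = maf_by_cohort(small_genotypes, vid, np.zeros(small_genotypes.n_individuals))
        assert table["maf"].iloc[0] == pytest.approx(small_genotypes.maf()[0])
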