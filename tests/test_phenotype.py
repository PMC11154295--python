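"""Effect-size draws, variance-partition trait simulation, binarization."""

import numpy as np
import pytest

from gwasim import phenotype
from gwasim.phenotype import PhenotypeParams

from conftest import make_genotypes


def random_genotypes(n, k, seed=0, maf_low=0.1, maf_high=0.5):
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=k)
    d = rng.binomial(2, p, size=(n, k)).astype(np.int8)
    return make_genotypes(d)


class TestDrawEffects:
    def test_degenerate_distribution(self):
        params = PhenotypeParams(sd_beta=0.0, random_sign=False)
        beta = phenotype.draw_effects(10, params, seed=0)
        np.testing.assert_array_equal(beta, np.full(10, 0.05))

    def test_default_mean_magnitude(self):
        params = PhenotypeParams()  # m_beta=0.05, sd_beta=0.001
        beta = phenotype.draw_effects(10_000, params, seed=1)
        assert abs(np.abs(beta).mean() - 0.05) < 4 * 0.001 / np.sqrt(10_000)

    def test_sign_randomization_is_balanced(self):
        params = PhenotypeParams(random_sign=True)
        beta = phenotype.draw_effects(10_000, params, seed=2)
        frac_neg = (beta < 0).mean()
        # binomial 99% bound around 0.5
        assert abs(frac_neg - 0.5) < 2.576 * 0.5 / np.sqrt(10_000)


class TestSimulateQuantitative:
    def test_variance_fraction_equals_h2_exactly(self):
        geno = random_genotypes(500, 10, seed=3)
        for h2 in (0.0, 0.01, 0.1, 0.5, 0.9):
            params = PhenotypeParams(h2=h2)
            beta = phenotype.draw_effects(10, params, seed=4)
            ph = phenotype.simulate_quantitative(geno, beta, params, seed=5)
            assert abs(ph.genetic_variance_fraction() - h2) < 1e-9

    def test_r2_on_genetic_component_equals_h2(self):
        geno = random_genotypes(10_000, 10, seed=6)
        params = PhenotypeParams()  # h2 = 0.1
        beta = phenotype.draw_effects(10, params, seed=7)
        ph = phenotype.simulate_quantitative(geno, beta, params, seed=8)
        # OLS oracle: R^2 of values on the stored genetic component
        g = ph.genetic - ph.genetic.mean()
        y = ph.values - ph.values.mean()
        r2 = (g @ y) ** 2 / ((g @ g) * (y @ y))
        assert abs(r2 - 0.1) < 1e-6

    def test_null_heritability_gives_pure_orthogonal_noise(self):
        geno = random_genotypes(1000, 5, seed=9)
        params = PhenotypeParams(h2=0.0)
        beta = phenotype.draw_effects(5, params, seed=10)
        ph = phenotype.simulate_quantitative(geno, beta, params, seed=11)
        np.testing.assert_allclose(ph.genetic, 0.0)
        # noise is residualized against the causal score, so exactly orthogonal
        Z = (geno.dosages - geno.dosages.mean(0)) / geno.dosages.std(0)
        score = Z @ beta
        assert abs(np.corrcoef(ph.values, score)[0, 1]) < 1e-10

    def test_same_seed_identical(self):
        geno = random_genotypes(200, 5, seed=12)
        params = PhenotypeParams()
        beta = phenotype.draw_effects(5, params, seed=13)
        a = phenotype.simulate_quantitative(geno, beta, params, seed=14)
        b = phenotype.simulate_quantitative(geno, beta, params, seed=14)
        np.testing.assert_array_equal(a.values, b.values)

    def test_hs2_below_one_requires_background(self):
        geno = random_genotypes(200, 5, seed=15)
        params = PhenotypeParams(hs2=0.5)
        beta = phenotype.draw_effects(5, params, seed=16)
        with pytest.raises(ValueError, match="background"):
            phenotype.simulate_quantitative(geno, beta, params, seed=17)

    def test_hs2_one_ignores_background(self):
        geno = random_genotypes(300, 5, seed=18)
        bg = random_genotypes(300, 50, seed=19)
        params = PhenotypeParams(hs2=1.0)
        beta = phenotype.draw_effects(5, params, seed=20)
        a = phenotype.simulate_quantitative(geno, beta, params, seed=21)
        b = phenotype.simulate_quantitative(geno, beta, params, background_genotypes=bg, seed=21)
        np.testing.assert_array_equal(a.values, b.values)

    def test_background_split_respects_h2_exactly(self):
        geno = random_genotypes(400, 5, seed=22)
        bg = random_genotypes(400, 100, seed=23)
        params = PhenotypeParams(h2=0.3, hs2=0.6)
        beta = phenotype.draw_effects(5, params, seed=24)
        ph = phenotype.simulate_quantitative(geno, beta, params, background_genotypes=bg, seed=25)
        assert abs(ph.genetic_variance_fraction() - 0.3) < 1e-9

    def test_zero_variance_causal_column_is_fatal(self):
        geno = random_genotypes(100, 3, seed=26)
        geno.dosages[:, 1] = 1
        params = PhenotypeParams()
        beta = phenotype.draw_effects(3, params, seed=27)
        with pytest.raises(ValueError, match="snp2"):
            phenotype.simulate_quantitative(geno, beta, params, seed=28)

    def test_non_default_shared_effect_parameters_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            PhenotypeParams(theta=0.5).validate()
        with pytest.raises(ValueError, match="phi"):
            PhenotypeParams(phi=0.8).validate()

    def test_association_strength_increases_with_h2(self):
        """Mean causal-variant chi-square rises across h2 in {0.01, 0.1, 0.5}."""
        from gwasim.association import assoc_quantitative

        geno = random_genotypes(2000, 5, seed=29)
        mean_chi2 = []
        for h2 in (0.01, 0.1, 0.5):
            vals = []
            for rep in range(10):
                params = PhenotypeParams(h2=h2)
                beta = phenotype.draw_effects(5, params, seed=100 + rep)
                ph = phenotype.simulate_quantitative(geno, beta, params, seed=200 + rep)
                stats = assoc_quantitative(geno, ph)
                vals.append((stats.table["stat"] ** 2).mean())
            mean_chi2.append(np.mean(vals))
        assert mean_chi2[0] < mean_chi2[1] < mean_chi2[2]


class TestBinarize:
    def make_pheno(self, values):
        values = np.asarray(values, dtype=float)
        return phenotype.PhenotypeVector(
            sample_ids=[f"s{i}" for i in range(len(values))],
            values=values,
            genetic=np.zeros(len(values)),
            noise=values,
        )

    def test_median_split(self):
        ph = self.make_pheno(np.arange(1, 11))
        labels = phenotype.binarize(ph, prevalence=0.5)
        np.testing.assert_array_equal(labels, [1] * 5 + [2] * 5)

    def test_exact_case_count(self):
        rng = np.random.default_rng(30)
        ph = self.make_pheno(rng.standard_normal(10_000))
        labels = phenotype.binarize(ph, prevalence=0.1)
        assert (labels == 2).sum() == 1000

    def test_tiny_prevalence_is_fatal(self):
        ph = self.make_pheno(np.arange(5))
        with pytest.raises(ValueError, match="no cases"):
            phenotype.binarize(ph, prevalence=0.01)

    def test_cases_enriched_for_causal_dosage_at_high_h2(self):
        """Liability model: case mean dosage exceeds control mean, more so at high h2."""
        geno = random_genotypes(2000, 3, seed=31)
        diffs = {}
        for h2 in (0.05, 0.8):
            gaps = []
            for rep in range(20):
                params = PhenotypeParams(h2=h2)
                beta = phenotype.draw_effects(3, params, seed=300 + rep)
                ph = phenotype.simulate_quantitative(geno, beta, params, seed=400 + rep)
                labels = phenotype.binarize(ph, prevalence=0.2)
                burden = (
                    np.sign(beta)
                    * (geno.dosages - geno.dosages.mean(0))
                    / geno.dosages.std(0)
                ).sum(axis=1)
                gaps.append(burden[labels == 2].mean() - burden[labels == 1].mean())
            diffs[h2] = np.mean(gaps)
        assert diffs[0.8] > diffs[0.05] > 0
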