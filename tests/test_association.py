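"""Per-SNP regression and allelic chi-square association tests."""

import numpy as np
import pytest
from scipy import stats as sps

from gwasim import association, phenotype
from gwasim.association import assoc_binary, assoc_quantitative, genomic_inflation

from conftest import make_genotypes


def pheno_from(values, sample_ids):
    values = np.asarray(values, dtype=float)
    return phenotype.PhenotypeVector(
        sample_ids=list(sample_ids), values=values,
        genetic=np.zeros(len(values)), noise=values,
    )


def ols_oracle(x, y):
    """Closed-form normal-equations simple regression with Wald t."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    b = sxy / sxx
    rss = syy - b * sxy
    se = np.sqrt(rss / (n - 2) / sxx)
    t = b / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    return b, se, t, p


class TestAssocQuantitative:
    def test_toy_table_matches_oracle(self):
        x = np.array([0, 1, 2, 0, 1, 2])
        y = np.array([0.1, 1.1, 2.0, 0.0, 0.9, 2.1])
        geno = make_genotypes(x[:, None])
        stats = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
        b, se, t, p = ols_oracle(x, y)
        row = stats.table.iloc[0]
        assert row["beta"] == pytest.approx(b, rel=1e-10)
        assert row["se"] == pytest.approx(se, rel=1e-10)
        assert row["stat"] == pytest.approx(t, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_hundred_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 3, size=n)
            if x.std() == 0:
                continue
            y = 0.3 * x + rng.standard_normal(n)
            geno = make_genotypes(x[:, None])
            stats = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
            b, se, t, p = ols_oracle(x, y)
            row = stats.table.iloc[0]
            assert row["beta"] == pytest.approx(b, rel=1e-10)
            assert row["se"] == pytest.approx(se, rel=1e-10)
            assert row["p"] == pytest.approx(p, rel=1e-10, abs=1e-300)

    def test_constant_phenotype_gives_p_one(self):
        rng = np.random.default_rng(1)
        geno = make_genotypes(rng.integers(0, 3, size=(30, 5)))
        stats = assoc_quantitative(geno, pheno_from(np.ones(30), geno.sample_ids))
        assert (stats.table["p"] == 1.0).all()

    def test_monomorphic_variant_keeps_row_with_p_one(self):
        d = np.ones((20, 2), dtype=np.int8)
        rng = np.random.default_rng(2)
        d[:, 1] = rng.integers(0, 3, size=20)
        geno = make_genotypes(d)
        y = rng.standard_normal(20)
        stats = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
        assert stats.table["p"].iloc[0] == 1.0
        assert stats.table["beta"].iloc[0] == 0.0
        assert np.isnan(stats.table["se"].iloc[0])
        assert len(stats) == 2

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        geno = make_genotypes(rng.binomial(2, 0.3, size=(300, 5000)))
        y = rng.standard_normal(300)  # permuted/independent phenotype
        stats = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
        ks = sps.kstest(stats.table["p"], "uniform").statistic
        assert ks < 1.63 / np.sqrt(5000)  # 99% critical value

    def test_sample_alignment_by_id(self):
        rng = np.random.default_rng(4)
        geno = make_genotypes(rng.integers(0, 3, size=(30, 3)))
        y = rng.standard_normal(30)
        direct = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
        perm = rng.permutation(30)
        shuffled = phenotype.PhenotypeVector(
            sample_ids=[geno.sample_ids[i] for i in perm], values=y[perm],
            genetic=np.zeros(30), noise=y[perm],
        )
        realigned = assoc_quantitative(geno, shuffled)
        np.testing.assert_allclose(realigned.table["p"], direct.table["p"])

    def test_id_mismatch_is_fatal(self):
        rng = np.random.default_rng(5)
        geno = make_genotypes(rng.integers(0, 3, size=(10, 2)))
        bad = pheno_from(rng.standard_normal(10), [f"x{i}" for i in range(10)])
        with pytest.raises(ValueError, match="mismatch"):
            assoc_quantitative(geno, bad)


class TestAssocBinary:
    def test_contingency_oracle(self):
        # cases: alt=30 ref=70; controls: alt=10 ref=90 (50 cases, 50 controls)
        d = np.zeros(100, dtype=np.int8)
        d[:15] = 2  # 30 alt alleles in first 15 cases
        d[50:55] = 2  # 10 alt alleles in controls
        geno = make_genotypes(d[:, None])
        labels = np.array([2] * 50 + [1] * 50)
        stats = assoc_binary(geno, labels)
        a, b, c, dd = 30, 70, 10, 90
        n = a + b + c + dd
        chi2 = n * (a * dd - b * c) ** 2 / ((a + b) * (c + dd) * (a + c) * (b + dd))
        row = stats.table.iloc[0]
        assert row["stat"] == pytest.approx(chi2, rel=1e-12)
        assert row["odds_ratio"] == pytest.approx((30 * 90) / (70 * 10), rel=1e-12)
        assert row["p"] == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-12)

    def test_equal_frequencies_give_null(self):
        d = np.array([2] * 10 + [0] * 10 + [2] * 10 + [0] * 10, dtype=np.int8)
        geno = make_genotypes(d[:, None])
        labels = np.array([2] * 20 + [1] * 20)
        stats = assoc_binary(geno, labels)
        assert stats.table["stat"].iloc[0] == 0.0
        assert stats.table["p"].iloc[0] == 1.0

    def test_zero_cell_uses_continuity_correction(self):
        d = np.array([2] * 10 + [0] * 10, dtype=np.int8)
        geno = make_genotypes(d[:, None])
        labels = np.array([2] * 10 + [1] * 10)  # all alt in cases
        stats = assoc_binary(geno, labels)
        assert np.isfinite(stats.table["odds_ratio"].iloc[0])
        assert stats.table["odds_ratio"].iloc[0] > 1

    def test_empty_class_is_fatal(self):
        geno = make_genotypes(np.ones((10, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="non-empty"):
            assoc_binary(geno, np.full(10, 2))


class TestGenomicInflation:
    def test_null_median_p_gives_lambda_one(self):
        p = np.full(101, sps.chi2.sf(association.CHI2_1DF_MEDIAN, 1))
        geno = make_genotypes(np.zeros((5, 101), dtype=np.int8))
        table = geno.variants.assign(a1="G", beta=0.0, se=1.0, stat=0.0, p=p, n=5)
        stats = association.SummaryStats(table=table, trait_type="quantitative")
        assert genomic_inflation(stats) == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation_lambda_near_one(self):
        rng = np.random.default_rng(6)
        lams = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            geno = make_genotypes(rng.binomial(2, 0.3, size=(200, 10_000)))
            y = rng.standard_normal(200)
            stats = assoc_quantitative(geno, pheno_from(y, geno.sample_ids))
            lams.append(genomic_inflation(stats))
        assert all(0.9 <= l <= 1.1 for l in lams)
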