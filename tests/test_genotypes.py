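"""Panel loading, filtering, mosaic simulation, and merging."""

import numpy as np
import pandas as pd
import pytest

from gwasim import fixtures, genotypes

from conftest import make_genotypes


def write_vcf(path, lines, samples=("s1", "s2", "s3", "s4")):
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + lines) + "\n")
    return str(path)


class TestLoadPanel:
    def test_phased_biallelic_records_ingested(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "p.vcf",
            [
                "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\t0|0\t0|1",
                "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|0\t0|1\t0|0\t0|0",
                "1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1|1\t1|1\t0|1\t1|0",
            ],
        )
        panel = genotypes.load_panel(vcf)
        assert panel.n_haplotypes == 8
        assert panel.n_variants == 3
        assert panel.variants["id"].tolist() == ["rs1", "rs2", "rs3"]
        # folded allele frequencies from direct counting
        np.testing.assert_allclose(panel.variants["maf"], [4 / 8, 1 / 8, 2 / 8])

    def test_unphased_record_excluded_and_counted(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "p.vcf",
            [
                "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\t0|0\t0|1",
                "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0|1\t0|0\t0|0",
            ],
        )
        panel = genotypes.load_panel(vcf)
        assert panel.n_variants == 1
        assert panel.n_skipped_records == 1

    def test_multiallelic_and_missing_skipped(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "p.vcf",
            [
                "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0|1\t1|2\t0|0\t0|1",
                "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t.|.\t0|1\t0|0\t0|0",
                "1\t300\trs3\tG\tA\t.\t.\t.\tGT\t0|1\t0|1\t0|0\t0|0",
            ],
        )
        panel = genotypes.load_panel(vcf)
        assert panel.variants["id"].tolist() == ["rs3"]
        assert panel.n_skipped_records == 2

    def test_no_usable_records_is_fatal(self, tmp_path):
        vcf = write_vcf(tmp_path / "p.vcf", ["1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t0/1\t0/0\t0/0"])
        with pytest.raises(ValueError, match="no usable"):
            genotypes.load_panel(vcf)

    def test_fixture_panel_maf_matches_brute_force_count(self, tmp_path, panel):
        path = tmp_path / "fixture.vcf"
        genotypes.write_panel_vcf(panel, str(path))
        reloaded = genotypes.load_panel(str(path))
        # brute-force allele count straight from the VCF text
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            alleles = "".join(fields[9:]).replace("|", "")
            alt = alleles.count("1")
            maf = min(alt, len(alleles) - alt) / len(alleles)
            row = reloaded.variants.loc[reloaded.variants["id"] == fields[2]]
            assert row["maf"].iloc[0] == pytest.approx(maf)


class TestFilterPanel:
    def test_maf_threshold_is_inclusive(self, tmp_path):
        # 100 haplotypes -> MAFs 0.01, 0.05, 0.30
        h = 100
        haps = np.zeros((h, 3), dtype=np.uint8)
        haps[:1, 0] = 1
        haps[:5, 1] = 1
        haps[:30, 2] = 1
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [100, 200, 300], "id": ["a", "b", "c"],
             "ref": "A", "alt": "G", "maf": [0.01, 0.05, 0.30]}
        )
        panel = genotypes.HaplotypePanel(variants=variants, haplotypes=haps,
                                         sample_ids=[f"s{i}" for i in range(h // 2)])
        out = genotypes.filter_panel(panel, min_maf=0.05)
        assert out.variants["id"].tolist() == ["b", "c"]

    def test_no_filtering_is_identity(self, panel):
        out = genotypes.filter_panel(panel, min_maf=0.0, keep_ids=panel.sample_ids)
        assert out.n_variants == panel.n_variants
        assert out.sample_ids == panel.sample_ids
        np.testing.assert_array_equal(out.haplotypes, panel.haplotypes)

    def test_keep_list_halves_panel_and_recomputes_maf(self, panel):
        keep = panel.sample_ids[: len(panel.sample_ids) // 2]
        out = genotypes.filter_panel(panel, min_maf=0.0, keep_ids=keep)
        assert out.n_haplotypes == panel.n_haplotypes // 2
        # brute-force recount on the kept haplotype rows
        kept_rows = panel.haplotypes[: panel.n_haplotypes // 2]
        counts = kept_rows.sum(axis=0)
        expect = np.minimum(counts, kept_rows.shape[0] - counts) / kept_rows.shape[0]
        np.testing.assert_allclose(out.variants["maf"], expect)

    def test_disjoint_keep_list_is_fatal(self, panel):
        with pytest.raises(ValueError, match="keep-list"):
            genotypes.filter_panel(panel, keep_ids=["nobody"])


class TestSimulateGenotypes:
    def test_degenerate_panel_of_identical_haplotypes(self):
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [100, 200, 300], "id": ["a", "b", "c"],
             "ref": "A", "alt": "G", "maf": [0.5, 0.5, 0.5]}
        )
        hap = np.array([1, 0, 1], dtype=np.uint8)
        panel = genotypes.HaplotypePanel(
            variants=variants, haplotypes=np.stack([hap, hap]), sample_ids=["s1"]
        )
        geno = genotypes.simulate_genotypes(panel, 20, switch_rate=0.5, seed=1)
        np.testing.assert_array_equal(geno.dosages, np.tile(2 * hap, (20, 1)))

    def test_zero_switch_rate_copies_panel_haplotypes(self):
        tiny = fixtures.make_panel(fixtures.FixtureConfig(n_diploids=4, n_snps=30, n_blocks=3, n_genes=5, seed=2))
        geno = genotypes.simulate_genotypes(tiny, 25, switch_rate=0.0, seed=3)
        # every dosage row must decompose into a sum of two panel haplotypes
        pairs = [
            a.astype(int) + b.astype(int) for a in tiny.haplotypes for b in tiny.haplotypes
        ]
        for row in geno.dosages:
            assert any(np.array_equal(row, pair) for pair in pairs)

    def test_allele_frequency_preserved_at_large_n(self, panel):
        geno = genotypes.simulate_genotypes(panel, 10000, switch_rate=0.002, seed=9)
        p_panel = panel.haplotypes.mean(axis=0)
        p_sim = geno.dosages.mean(axis=0) / 2.0
        se = np.sqrt(p_panel * (1 - p_panel) / (2 * geno.n_samples))
        within = np.abs(p_sim - p_panel) <= 3 * se
        assert within.mean() >= 0.99

    def test_adjacent_ld_decreases_with_switch_rate(self, panel):
        def mean_adjacent_r2(sw):
            geno = genotypes.simulate_genotypes(panel, 4000, switch_rate=sw, seed=11)
            X = geno.dosages.astype(float)
            X = X[:, X.std(axis=0) > 0]
            r = [
                np.corrcoef(X[:, j], X[:, j + 1])[0, 1] ** 2
                for j in range(0, X.shape[1] - 1, 7)
            ]
            return np.mean(r)

        r2 = [mean_adjacent_r2(sw) for sw in (0.0, 0.05, 0.5)]
        assert r2[0] > r2[1] > r2[2]

    def test_same_seed_is_bit_identical(self, panel):
        a = genotypes.simulate_genotypes(panel, 30, seed=5)
        b = genotypes.simulate_genotypes(panel, 30, seed=5)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_empty_panel_is_fatal(self, panel):
        empty = genotypes.HaplotypePanel(
            variants=panel.variants.iloc[:0], haplotypes=panel.haplotypes[:, :0],
            sample_ids=panel.sample_ids,
        )
        with pytest.raises(ValueError, match="empty panel"):
            genotypes.simulate_genotypes(empty, 10)


class TestMergePanels:
    def make_part(self, chrom, m, offset=0):
        rng = np.random.default_rng(hash(chrom) % 1000)
        dosages = rng.integers(0, 3, size=(10, m)).astype(np.int8)
        return make_genotypes(
            dosages, chrom=chrom, pos=1000 + 100 * np.arange(m),
            ids=[f"{chrom}_snp{j + offset}" for j in range(m)],
        )

    def test_concatenation_and_order(self):
        a, b = self.make_part("1", 5), self.make_part("2", 7)
        merged = genotypes.merge_panels([a, b])
        assert merged.n_variants == 12
        assert merged.variants["chrom"].tolist() == ["1"] * 5 + ["2"] * 7

    def test_reverse_part_order_gives_same_result(self):
        a, b = self.make_part("1", 5), self.make_part("2", 7)
        fwd = genotypes.merge_panels([a, b])
        rev = genotypes.merge_panels([b, a])
        pd.testing.assert_frame_equal(fwd.variants, rev.variants)
        np.testing.assert_array_equal(fwd.dosages, rev.dosages)

    def test_duplicate_variant_id_is_fatal(self):
        a, b = self.make_part("1", 5), self.make_part("2", 5)
        b.variants.loc[0, "id"] = a.variants["id"].iloc[0]
        with pytest.raises(ValueError, match="duplicate variant id"):
            genotypes.merge_panels([a, b])

    def test_sample_mismatch_is_fatal(self):
        a, b = self.make_part("1", 5), self.make_part("2", 5)
        b.sample_ids = [s + "x" for s in b.sample_ids]
        with pytest.raises(ValueError, match="sample ids differ"):
            genotypes.merge_panels([a, b])


class TestRoundTrips:
    def test_genotype_vcf_round_trip(self, tmp_path, small_genotypes):
        path = tmp_path / "g.vcf"
        genotypes.write_genotype_vcf(small_genotypes, str(path))
        back = genotypes.load_genotypes(str(path))
        np.testing.assert_array_equal(back.dosages, small_genotypes.dosages)
        assert back.sample_ids == small_genotypes.sample_ids
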