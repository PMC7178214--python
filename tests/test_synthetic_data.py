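"""Generator correctness: copula LD structure, cohort resampling,
regression summary statistics against a by-hand oracle, and the null-GWAS
negative control."""

import inspect

import numpy as np
import pytest
from scipy import stats

from convergene.synthetic_data import (SimScenario, compute_summary_stats,
                                       designated_esnp_index,
                                       make_expression_groups,
                                       make_haplotype_panel, make_null_gwas,
                                       read_panel_tsv, read_panel_vcf,
                                       simulate_cohort, simulate_eqtl_dataset,
                                       simulate_expression_and_phenotype,
                                       simulate_study, write_panel_tsv)


def _scenario(**kw):
    base = dict(n_genes=4, n_snps_per_gene=2, n_eqtl_cohort=100,
                n_gwas_cohort=100, n_null_cohort=100,
                n_replication_cohort=100, n_panel=500, seed=0)
    base.update(kw)
    return SimScenario(**base)


class TestHaplotypePanel:
    def test_determinism_same_seed(self):
        sc = _scenario(seed=5)
        a, b = make_haplotype_panel(sc), make_haplotype_panel(sc)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.blocks == b.blocks

    def test_rho_zero_gives_independent_snps(self):
        panel = make_haplotype_panel(_scenario(block_rho=0.0, n_panel=500))
        G = panel.genotypes().astype(float)
        r = np.corrcoef(G.T)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.2 and np.abs(off).mean() < 0.05

    def test_rho_high_equal_freqs_gives_strong_ld(self):
        # equal frequencies at 0.5 minimize the binary-thresholding
        # attenuation; latent rho 0.99 then gives dosage r^2 ~ 0.83
        sc = _scenario(block_rho=0.99, n_panel=1000)
        panel = make_haplotype_panel(sc, freqs=[0.5, 0.5])
        G = panel.genotypes().astype(float)
        for lo, hi, _ in panel.blocks:
            r = np.corrcoef(G[:, lo], G[:, hi - 1])[0, 1]
            assert r ** 2 > 0.8

    def test_allele_frequencies_polymorphic_and_increasing_pos(self):
        panel = make_haplotype_panel(_scenario(n_panel=50))
        f = panel.allele_freq()
        assert ((f > 0) & (f < 1)).all()
        assert (np.diff(panel.snps["pos"].to_numpy()) > 0).all()


class TestCohort:
    def test_entries_and_shape(self, small_panel):
        G = simulate_cohort(small_panel, 1, seed=1)
        assert G.shape == (1, small_panel.n_snps)
        assert set(np.unique(G)) <= {0, 1, 2}

    def test_reproducible(self, small_panel):
        a = simulate_cohort(small_panel, 10, seed=3)
        b = simulate_cohort(small_panel, 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_cohort_frequencies_track_panel(self, small_panel):
        n = 800
        G = simulate_cohort(small_panel, n, seed=2)
        f_panel = small_panel.allele_freq()
        f_cohort = G.mean(axis=0) / 2.0
        se = np.sqrt(f_panel * (1 - f_panel) / (2 * n))
        assert (np.abs(f_cohort - f_panel) < 4 * se + 1e-9).mean() > 0.99


class TestSummaryStats:
    def test_by_hand_least_squares(self):
        dosage = np.array([[0], [1], [2], [0], [1], [2]], dtype=float)
        trait = np.array([0.1, 1.1, 2.2, -0.1, 0.9, 2.0])
        df, excluded = compute_summary_stats(dosage, trait, ["s"])
        # independent oracle: plain-python simple linear regression
        x, y = dosage[:, 0], trait
        n = len(x)
        xm, ym = sum(x) / n, sum(y) / n
        sxx = sum((xi - xm) ** 2 for xi in x)
        sxy = sum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
        beta = sxy / sxx
        rss = sum((yi - ym - beta * (xi - xm)) ** 2 for xi, yi in zip(x, y))
        se = (rss / (n - 2) / sxx) ** 0.5
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        assert excluded == []
        assert df.loc[0, "z"] == pytest.approx(z, abs=1e-10)
        assert df.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_perfect_association_clamped(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(50, 1)).astype(float)
        df, _ = compute_summary_stats(dosage, dosage[:, 0], ["s"])
        assert 0 < df.loc[0, "p"] < 1e-300

    def test_monomorphic_snp_excluded(self):
        G = np.column_stack([np.ones(10), np.arange(10) % 3])
        df, excluded = compute_summary_stats(G, np.arange(10.0), ["mono", "ok"])
        assert excluded == ["mono"]
        assert list(df["snp_id"]) == ["ok"]

    def test_permuted_trait_gives_uniform_p(self):
        sc = _scenario(n_genes=250, n_snps_per_gene=2, block_rho=0.0,
                       n_panel=300, seed=9)
        panel = make_haplotype_panel(sc)
        G = simulate_cohort(panel, 1000, seed=9)
        y = np.random.default_rng(9).permutation(G[:, 0]).astype(float)
        df, _ = compute_summary_stats(G[:, 1:], y, panel.snp_ids[1:])
        assert stats.kstest(df["p"], "uniform").pvalue > 0.01


class TestExpressionAndPhenotype:
    def test_deterministic(self, small_panel, small_scenario):
        G = simulate_cohort(small_panel, 50, seed=4)
        a = simulate_expression_and_phenotype(G, small_scenario, seed=4)
        b = simulate_expression_and_phenotype(G, small_scenario, seed=4)
        np.testing.assert_array_equal(a[0].to_numpy(), b[0].to_numpy())
        np.testing.assert_array_equal(a[1], b[1])

    def test_global_null_no_association(self):
        sc = _scenario(n_genes=100, n_snps_per_gene=2, eqtl_effect=0.0,
                       mediation_effect=0.0, block_rho=0.0, n_panel=300, seed=3)
        panel = make_haplotype_panel(sc)
        G = simulate_cohort(panel, 2000, seed=3)
        _, y = simulate_expression_and_phenotype(G, sc, seed=3)
        df, _ = compute_summary_stats(G, y, panel.snp_ids)
        assert stats.kstest(df["p"], "uniform").pvalue > 0.01

    def test_eqtl_power_matches_noncentrality(self):
        # for the designated cis-eSNP, E[z^2] ~ 1 + n*be^2*2f(1-f)/var(x)
        sc = _scenario(n_genes=10, n_snps_per_gene=3, eqtl_effect=0.5,
                       block_rho=0.0, n_panel=400, seed=6, n_eqtl_cohort=2000)
        panel = make_haplotype_panel(sc)
        eqtl = simulate_eqtl_dataset(panel, sc, 2000, seed=6)
        esnp = designated_esnp_index(sc)
        p = {(r.gene_id, r.snp_id): r.p_value for r in eqtl}
        for gid in sc.gene_ids:
            snp = panel.snp_ids[esnp[gid]]
            assert p[(gid, snp)] < 1e-10

    def test_causal_esnps_carry_more_gwas_signal(self):
        # effect propagation, averaged over seeds
        z2_causal, z2_null = [], []
        for seed in range(50):
            sc = _scenario(n_genes=10, n_snps_per_gene=1,
                           causal_gene_ids=frozenset({"G0001", "G0002"}),
                           n_gwas_cohort=500, n_panel=150, block_rho=0.0,
                           seed=seed)
            panel = make_haplotype_panel(sc)
            G = simulate_cohort(panel, sc.n_gwas_cohort, seed=seed + 1000)
            _, y = simulate_expression_and_phenotype(G, sc, seed=seed + 1000)
            df, _ = compute_summary_stats(G, y, panel.snp_ids)
            esnp = designated_esnp_index(sc)
            df = df.set_index("snp_id")
            for gid in sc.gene_ids:
                z2 = df.loc[panel.snp_ids[esnp[gid]], "z"] ** 2
                (z2_causal if gid in sc.causal else z2_null).append(z2)
        assert np.mean(z2_causal) > np.mean(z2_null)


class TestNullGwas:
    def test_default_cohort_size(self):
        sig = inspect.signature(make_null_gwas)
        assert sig.parameters["n"].default == 3960

    def test_null_p_uniform_and_type1(self):
        # panel much larger than the cohort: haplotype-resampling overlap
        # between individuals is negligible, so the 2000 SNP p-values are
        # effectively independent and the binomial band applies
        sc = _scenario(n_genes=1000, n_snps_per_gene=2, block_rho=0.0,
                       n_panel=5000, seed=12)
        panel = make_haplotype_panel(sc)
        records = make_null_gwas(panel, n=500, seed=12)
        p = np.array([r.p_value for r in records])
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert 0.04 <= (p < 0.05).mean() <= 0.06

    def test_records_carry_positions_and_maf(self, small_panel):
        records = make_null_gwas(small_panel, n=100, seed=1)
        assert all(r.pos is not None and 0 < r.maf <= 0.5 for r in records)


class TestExpressionGroups:
    def test_group_sizes_and_labels(self):
        m = make_expression_groups(10, 10, ["A"], seed=0)
        assert m.group.count("low") == 10 and m.group.count("high") == 10
        m2 = make_expression_groups(9, 10, ["A"], seed=0)
        assert m2.group.count("low") == 9 and m2.group.count("high") == 10

    def test_shift_raises_low_group_mean(self):
        m = make_expression_groups(10, 10, ["DE1"], de_shift=2.0, seed=1,
                                   gene_ids=["DE1", "BG1"])
        de_row = m.values[0]
        assert de_row[:10].mean() - de_row[10:].mean() > 0.5

    def test_null_shift_gives_uniform_t_p(self):
        m = make_expression_groups(10, 10, [], de_shift=0.0, seed=2,
                                   gene_ids=[f"g{i}" for i in range(500)])
        low, high = m.group_values("low"), m.group_values("high")
        p = stats.ttest_ind(low, high, axis=1).pvalue
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBundleAndPanelIO:
    def test_bundle_cross_references(self, small_bundle):
        gwas_ids = {r.snp_id for r in small_bundle.gwas}
        assert {r.snp_id for r in small_bundle.eqtl} <= gwas_ids
        gene_ids = {g.gene_id for g in small_bundle.genes}
        assert {r.gene_id for r in small_bundle.eqtl} <= gene_ids
        assert set(small_bundle.truth.query("causal").gene_id) == \
            set(small_bundle.scenario.causal)

    def test_panel_tsv_round_trip(self, tmp_path):
        panel = make_haplotype_panel(_scenario(n_panel=20, seed=2))
        write_panel_tsv(panel, tmp_path / "panel.tsv")
        back = read_panel_tsv(tmp_path / "panel.tsv")
        np.testing.assert_array_equal(back.haplotypes, panel.haplotypes)
        assert back.blocks == panel.blocks
        assert list(back.snps["pos"]) == list(panel.snps["pos"])

    def test_panel_vcf_reader(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\n"
            "1\t100\trsA\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
            "1\t200\trsB\tC\tT\t.\t.\t.\tGT\t0|0\t0|1\n"
        )
        panel = read_panel_vcf(vcf)
        assert panel.snp_ids == ["rsA", "rsB"]
        np.testing.assert_array_equal(
            panel.haplotypes, np.array([[0, 0], [1, 0], [1, 0], [1, 1]]))
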