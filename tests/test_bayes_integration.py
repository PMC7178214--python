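"""The log-Bayes-factor scoring stage: closed-form per-SNP score, eSNP
detection and pruning, the simulated null, and gene-level behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from convergene.bayes_integration import (BayesConfig, NullLbfSampler,
                                          _greedy_prune, detect_esnps,
                                          lbf_from_z, prune_esnps, replicate,
                                          sample_null_lbf, score_genes,
                                          snp_lbf)
from convergene.io_formats import EqtlRecord, GwasSnpRecord
from convergene.synthetic_data import SimScenario, simulate_study


CFG = BayesConfig(null_draws=50_000)


class TestSnpLbf:
    def test_null_p_gives_negative_intercept(self):
        # z = 0: LBF = 0.5*log10(1/(1+W)) = 0.5*log10(1/5)
        assert snp_lbf(1.0, CFG) == pytest.approx(0.5 * math.log10(0.2), abs=1e-9)

    def test_strong_signal_closed_form(self):
        # z = 5, W = 4: -0.34949 + 12.5 * 0.8 * log10(e) = 3.9935
        p = 2 * stats.norm.sf(5.0)
        expected = 0.5 * math.log10(0.2) + 12.5 * 0.8 * math.log10(math.e)
        assert snp_lbf(p, CFG) == pytest.approx(expected, abs=1e-6)
        assert snp_lbf(p, CFG) == pytest.approx(3.9935, abs=1e-3)

    def test_sign_boundary(self):
        z = math.sqrt(CFG.lbf_sign_boundary_z2)
        p = 2 * stats.norm.sf(z)
        assert snp_lbf(p, CFG) == pytest.approx(0.0, abs=1e-9)
        assert snp_lbf(2 * stats.norm.sf(z + 0.01), CFG) > 0
        assert snp_lbf(2 * stats.norm.sf(z - 0.01), CFG) < 0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            snp_lbf(bad, CFG)

    @given(st.floats(0.0, 8.0), st.floats(0.0, 8.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_even_and_increasing_in_abs_z(self, z1, z2):
        lo, hi = sorted([z1, z2])
        assert lbf_from_z(-lo, CFG) == pytest.approx(float(lbf_from_z(lo, CFG)))
        if hi > lo:
            assert lbf_from_z(hi, CFG) > lbf_from_z(lo, CFG)


class TestDetectEsnps:
    def test_threshold_is_strict_and_motivating_esnp_qualifies(self):
        eqtl = [EqtlRecord("rs7475", "PPP1CB", 2.10e-6),
                EqtlRecord("rs_weak", "PPP1CB", 0.5),
                EqtlRecord("rs_at", "OTHER", 1e-5)]
        found = detect_esnps(eqtl, CFG)
        assert found == {"PPP1CB": {"rs7475"}}

    def test_empty_input(self):
        assert detect_esnps([], CFG) == {}


class TestPruning:
    def test_perfect_proxies_keep_best_eqtl_p(self, small_panel):
        # two ids sharing one haplotype column -> r^2 = 1
        sid = small_panel.snp_ids
        kept = _greedy_prune(["a", "b"], np.ones((2, 2)), 0.2)
        assert kept == ["a"]
        eqtl_p = {sid[0]: 1e-8, sid[1]: 1e-6}
        # self-pruning a single snp is a no-op
        assert prune_esnps([sid[0]], eqtl_p, small_panel, CFG) == [sid[0]]

    def test_independent_set_unchanged(self):
        r2 = np.eye(3)
        assert _greedy_prune(["a", "b", "c"], r2, 0.2) == ["a", "b", "c"]

    def test_greedy_chain(self):
        # r^2: A-B 0.9, B-C 0.9, A-C 0.1; priority A < B < C -> keep {A, C}
        r2 = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        assert _greedy_prune(["A", "B", "C"], r2, 0.2) == ["A", "C"]

    def test_missing_snp_named(self, small_panel):
        with pytest.raises(KeyError, match="rs_missing"):
            prune_esnps(["rs_missing"], {"rs_missing": 1e-8}, small_panel, CFG)


class TestNullSampler:
    def test_worst_observed_score_has_p_near_one(self):
        sampler = NullLbfSampler(CFG, seed=0)
        assert sampler.p_value(-1e9, 1) == 1.0

    def test_p_floor_is_add_one(self):
        sampler = NullLbfSampler(CFG, seed=0)
        assert sampler.p_value(1e9, 2) == 1.0 / (CFG.null_draws + 1)

    def test_positive_score_rate_matches_chi2_tail(self):
        draws, _ = sample_null_lbf(1, CFG, seed=1)
        expected = stats.chi2.sf(CFG.lbf_sign_boundary_z2, df=1)
        frac = (draws > 0).mean()
        se = math.sqrt(expected * (1 - expected) / draws.size)
        assert abs(frac - expected) < 3 * se

    def test_deterministic(self):
        a, pa = sample_null_lbf(2, CFG, seed=5, observed=1.0)
        b, pb = sample_null_lbf(2, CFG, seed=5, observed=1.0)
        np.testing.assert_array_equal(a, b)
        assert pa == pb


class TestScoreGenes:
    def _records(self):
        eqtl = [EqtlRecord("rs1", "GA", 1e-8), EqtlRecord("rs2", "GA", 1e-7),
                EqtlRecord("rs3", "GB", 1e-9), EqtlRecord("rs4", "GC", 0.9)]
        gwas = [GwasSnpRecord("rs1", 1e-6), GwasSnpRecord("rs2", 0.3),
                GwasSnpRecord("rs3", 0.5)]
        return eqtl, gwas

    def test_additivity_and_totals(self):
        eqtl, gwas = self._records()
        results = score_genes(eqtl, gwas, panel=None, config=CFG, seed=0)
        by_gene = {r.gene_id: r for r in results}
        ga = by_gene["GA"]
        assert ga.n_esnps == 2
        assert ga.lbf_total == pytest.approx(sum(ga.per_snp_lbf), abs=1e-9)
        assert ga.lbf_total == pytest.approx(
            snp_lbf(1e-6, CFG) + snp_lbf(0.3, CFG), abs=1e-9)
        # GC has no eSNP: not scored
        assert "GC" not in by_gene
        for r in results:
            assert r.p_corrected == pytest.approx(
                min(1.0, r.p_empirical * len(results)))
            assert r.p_empirical >= 1.0 / (CFG.null_draws + 1)

    def test_invariant_to_eqtl_record_order(self):
        eqtl, gwas = self._records()
        a = score_genes(eqtl, gwas, None, CFG, seed=0)
        b = score_genes(list(reversed(eqtl)), gwas, None, CFG, seed=0)
        assert a == b

    def test_unmatched_esnps_dropped_with_warning(self, caplog):
        eqtl = [EqtlRecord("rs1", "GA", 1e-8), EqtlRecord("rs_nogwas", "GA", 1e-8)]
        gwas = [GwasSnpRecord("rs1", 0.01)]
        with caplog.at_level("WARNING"):
            results = score_genes(eqtl, gwas, None, CFG, seed=0)
        assert results[0].esnp_ids == ("rs1",)
        assert "rs_nogwas" in caplog.text

    def test_no_scoreable_genes_raises(self):
        with pytest.raises(ValueError):
            score_genes([EqtlRecord("rs1", "GA", 0.9)],
                        [GwasSnpRecord("rs1", 0.5)], None, CFG, seed=0)

    def test_recovery_in_small_scenario(self, small_bundle):
        results = score_genes(small_bundle.eqtl, small_bundle.gwas,
                              small_bundle.panel, CFG,
                              seed=small_bundle.scenario.seed)
        top5 = {r.gene_id for r in
                sorted(results, key=lambda r: -r.lbf_total)[:5]}
        assert small_bundle.scenario.causal <= top5

    def test_mediation_effect_monotonicity(self):
        means = []
        for beta_m in (0.0, 0.15, 0.3):
            totals = []
            for seed in range(6):
                sc = SimScenario(n_genes=40, n_snps_per_gene=2,
                                 causal_gene_ids=frozenset({"G0001", "G0002", "G0003"}),
                                 mediation_effect=beta_m, n_eqtl_cohort=600,
                                 n_gwas_cohort=2000, n_panel=150,
                                 block_rho=0.0, seed=seed)
                b = simulate_study(sc)
                res = score_genes(b.eqtl, b.gwas, b.panel, CFG, seed=seed)
                totals += [r.lbf_total for r in res if r.gene_id in sc.causal]
            means.append(np.mean(totals))
        assert means[0] <= means[1] <= means[2]


class TestReplicate:
    def _result(self, gene, p_emp, p_corr, lbf=1.0):
        from convergene.bayes_integration import GeneIntegrationResult
        return GeneIntegrationResult(gene, ("rs1",), (lbf,), lbf, p_emp,
                                     p_corr, 1)

    def test_flags(self):
        disc = [self._result("GA", 1e-5, 1e-3), self._result("GB", 0.5, 1.0)]
        repl = [self._result("GA", 0.01, 0.04)]
        df = replicate(disc, repl).set_index("gene_id")
        assert bool(df.loc["GA", "significant_discovery"])
        assert bool(df.loc["GA", "validated"])
        assert bool(df.loc["GA", "both_corrected"])
        # absent from replication -> missing, not False
        assert df.loc["GB", "validated"] is not False
        assert df.loc["GB", "p_replication"] is not None

    def test_disjoint_universes_warn(self, caplog):
        disc = [self._result("GA", 0.5, 1.0)]
        repl = [self._result("GX", 0.5, 1.0)]
        with caplog.at_level("WARNING"):
            df = replicate(disc, repl)
        assert "intersect" in caplog.text
        assert df["validated"].isna().all()
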