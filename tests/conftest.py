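import pytest

from convergene.bayes_integration import BayesConfig
from convergene.synthetic_data import SimScenario, make_haplotype_panel, simulate_study


@pytest.fixture(scope="session")
def small_scenario():
    """A desk-scale scenario used by several module tests: 30 genes x 3
    SNPs, 2 causal genes, modest cohorts."""
    return SimScenario(
        n_genes=30,
        n_snps_per_gene=3,
        causal_gene_ids=frozenset({"G0001", "G0002"}),
        n_eqtl_cohort=500,
        n_gwas_cohort=1500,
        n_null_cohort=400,
        n_replication_cohort=250,
        n_panel=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return simulate_study(small_scenario)


@pytest.fixture(scope="session")
def small_panel(small_bundle):
    return small_bundle.panel


@pytest.fixture(scope="session")
def fast_bayes():
    """Bayes configuration with a reduced null sample for unit tests."""
    return BayesConfig(null_draws=50_000)
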