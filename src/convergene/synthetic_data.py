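"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generative model: LD-blocked haplotypes (one block per gene, drawn from
a latent Gaussian copula with exchangeable within-block correlation),
diploid cohorts resampled from the panel, gene expression driven by one
designated cis-eSNP per gene, and a quantitative phenotype mediated through
the expression of a small causal gene set:

    x_g = beta_e * G_c(g) + eps,        eps ~ N(0, 1)
    y   = beta_m * sum_{g in causal} x_g + delta,   delta ~ N(0, 1)

Per-SNP summary statistics are simple linear regressions of a trait on
allele dosage with a two-sided normal p-value.  A "null GWAS" draws the
phenotype independently of genotype, mirroring a random phenotype
reassignment negative control.  Everything is a pure function of
(scenario, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EqtlRecord, ExpressionMatrix, GeneModel, GwasSnpRecord

__all__ = [
    "SimScenario",
    "HaplotypePanel",
    "SummaryStatsBundle",
    "make_haplotype_panel",
    "simulate_cohort",
    "simulate_expression_and_phenotype",
    "compute_summary_stats",
    "make_null_gwas",
    "make_expression_groups",
    "simulate_study",
    "simulate_eqtl_dataset",
    "gene_models",
    "write_panel_tsv",
    "read_panel_tsv",
    "read_panel_vcf",
]

logger = logging.getLogger(__name__)

#: smallest positive representable double; p-values are clamped here so that
#: downstream log transforms never see zero.
P_FLOOR = np.nextafter(0.0, 1.0)

GENE_SPAN = 50_000       # bp covered by each simulated gene
GENE_SPACING = 1_000_000  # bp between gene starts; keeps +/-20 kb windows disjoint


@dataclass(frozen=True)
class SimScenario:
    """One simulation's parameters.

    ``eqtl_effect`` (beta_e) is the per-allele effect on expression in
    expression-SD units; ``mediation_effect`` (beta_m) the per-unit
    expression effect on the phenotype.  Cohort defaults mirror the source
    study's eQTL (n=1490), replication (n=400) and null-control (n=3960)
    sample sizes; the GWAS cohort is a desk-scale 5000.
    """

    n_genes: int = 200
    n_snps_per_gene: int = 5
    causal_gene_ids: frozenset[str] | None = None  # None -> first 5 genes
    eqtl_gene_ids: frozenset[str] | None = None    # None -> every gene
    eqtl_effect: float = 0.5
    mediation_effect: float = 0.3
    n_eqtl_cohort: int = 1490
    n_gwas_cohort: int = 5000
    n_null_cohort: int = 3960
    n_replication_cohort: int = 400
    n_panel: int = 500
    block_rho: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2 or self.n_snps_per_gene < 1:
            raise ValueError("need >= 2 genes and >= 1 SNP per gene")
        for name in ("n_eqtl_cohort", "n_gwas_cohort", "n_null_cohort",
                     "n_replication_cohort", "n_panel"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        universe = set(self.gene_ids)
        if self.causal_gene_ids is not None and not set(self.causal_gene_ids) <= universe:
            raise ValueError("causal_gene_ids must be a subset of the gene universe")
        if self.eqtl_gene_ids is not None and not set(self.eqtl_gene_ids) <= universe:
            raise ValueError("eqtl_gene_ids must be a subset of the gene universe")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def causal(self) -> frozenset[str]:
        if self.causal_gene_ids is not None:
            return frozenset(self.causal_gene_ids)
        return frozenset(self.gene_ids[: min(5, self.n_genes)])

    @property
    def eqtl_genes(self) -> frozenset[str]:
        if self.eqtl_gene_ids is not None:
            return frozenset(self.eqtl_gene_ids)
        return frozenset(self.gene_ids)


@dataclass
class HaplotypePanel:
    """Reference haplotypes: a (2*n_panel) x n_snps 0/1 matrix plus SNP
    metadata and the block structure used to generate it."""

    snps: pd.DataFrame  # columns: snp_id, chrom, pos, ref, alt
    haplotypes: np.ndarray
    blocks: list[tuple[int, int, float]]  # (start index, stop index, rho)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype columns must match SNP metadata rows")
        self._index = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        idx = []
        for s in snp_ids:
            if s not in self._index:
                raise KeyError(f"SNP {s!r} not present in the haplotype panel")
            idx.append(self._index[s])
        return np.asarray(idx, dtype=int)

    def genotypes(self) -> np.ndarray:
        """Panel haplotypes paired into n_panel diploid dosage rows."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class SummaryStatsBundle:
    """Everything a downstream stage consumes, plus the generating truth."""

    gwas: list[GwasSnpRecord]
    eqtl: list[EqtlRecord]
    genes: list[GeneModel]
    truth: pd.DataFrame  # gene_id, causal, esnp_id, eqtl_beta, mediation_beta
    panel: HaplotypePanel
    scenario: SimScenario


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def gene_models(scenario: SimScenario) -> list[GeneModel]:
    out = []
    for i, gid in enumerate(scenario.gene_ids):
        start = 1 + i * GENE_SPACING
        out.append(GeneModel(gene_id=gid, chrom="1", start=start,
                             end=start + GENE_SPAN - 1, strand="+"))
    return out


def _snp_metadata(scenario: SimScenario) -> pd.DataFrame:
    m = scenario.n_snps_per_gene
    rows = []
    for i in range(scenario.n_genes):
        start = 1 + i * GENE_SPACING
        for j in range(m):
            pos = start + (j + 1) * (GENE_SPAN // (m + 1))
            rows.append((f"rs{i * m + j + 1:06d}", "1", pos, "A", "G"))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])


def designated_esnp_index(scenario: SimScenario) -> dict[str, int]:
    """Global SNP column index of each gene's designated cis-eSNP (the
    middle SNP of its block)."""
    m = scenario.n_snps_per_gene
    return {gid: i * m + m // 2 for i, gid in enumerate(scenario.gene_ids)}


def make_haplotype_panel(
    scenario: SimScenario, freqs: Sequence[float] | None = None
) -> HaplotypePanel:
    """Draw haplotypes block-by-block from a latent Gaussian copula.

    Within a block the latent variables share exchangeable correlation
    ``block_rho``; each SNP's allele frequency is Uniform(0.05, 0.5) unless
    ``freqs`` (one value per SNP within a block, recycled across blocks)
    pins them.  Monomorphic columns (possible only in very small panels)
    are redrawn.
    """
    rng = _rng(scenario.seed, 0)
    H = 2 * scenario.n_panel
    m = scenario.n_snps_per_gene
    rho = scenario.block_rho
    if freqs is not None:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (m,) or not ((freqs > 0) & (freqs < 1)).all():
            raise ValueError("freqs must hold one frequency in (0,1) per block SNP")
    cols = []
    blocks = []
    for b in range(scenario.n_genes):
        block_freqs = (freqs.copy() if freqs is not None
                       else rng.uniform(0.05, 0.5, size=m))
        common = rng.standard_normal((H, 1))
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal((H, m))
        hap = (z < stats.norm.ppf(block_freqs)).astype(np.uint8)
        for _ in range(100):
            mono = (hap.min(axis=0) == hap.max(axis=0))
            if not mono.any():
                break
            k = int(mono.sum())
            zf = (np.sqrt(rho) * common + np.sqrt(1.0 - rho)
                  * rng.standard_normal((H, k)))
            hap[:, mono] = (zf < stats.norm.ppf(rng.uniform(0.05, 0.5, size=k))
                            ).astype(np.uint8)
        cols.append(hap)
        blocks.append((b * m, b * m + m, rho))
    return HaplotypePanel(snps=_snp_metadata(scenario),
                          haplotypes=np.hstack(cols), blocks=blocks)


def simulate_cohort(panel: HaplotypePanel, n: int, seed: int) -> np.ndarray:
    """Diploid genotypes: each individual is the sum of two haplotypes
    resampled with replacement from the panel.  Returns n x n_snps dosages."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = _rng(seed, 1)
    H = panel.haplotypes.shape[0]
    idx = rng.integers(0, H, size=2 * n)
    return (panel.haplotypes[idx[0::2]] + panel.haplotypes[idx[1::2]]).astype(np.int8)


def simulate_expression_and_phenotype(
    genotypes: np.ndarray, scenario: SimScenario, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression matrix (n x n_genes) and mediated phenotype vector."""
    rng = _rng(seed, 2)
    n = genotypes.shape[0]
    esnp = designated_esnp_index(scenario)
    X = rng.standard_normal((n, scenario.n_genes))
    for i, gid in enumerate(scenario.gene_ids):
        if gid in scenario.eqtl_genes:
            X[:, i] += scenario.eqtl_effect * genotypes[:, esnp[gid]]
    causal_cols = [i for i, gid in enumerate(scenario.gene_ids)
                   if gid in scenario.causal]
    y = scenario.mediation_effect * X[:, causal_cols].sum(axis=1)
    y = y + rng.standard_normal(n)
    return pd.DataFrame(X, columns=scenario.gene_ids), y


def compute_summary_stats(
    genotypes: np.ndarray, trait: np.ndarray, snp_ids: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-SNP simple linear regression of ``trait`` on allele dosage.

    Returns a frame with columns snp_id/beta/se/z/p (two-sided normal tail,
    clamped at the smallest positive double) plus the list of monomorphic
    SNPs excluded from the output.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = G.shape[0]
    if y.shape[0] != n:
        raise ValueError("trait length must equal cohort size")
    if n < 3:
        raise ValueError("need >= 3 observations for a regression")
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    poly = sxx > 0
    excluded = [s for s, ok in zip(snp_ids, poly) if not ok]
    if excluded:
        logger.warning("excluding %d monomorphic SNPs from summary stats",
                       len(excluded))
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = gc.T @ yc
        beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
        syy = float((yc ** 2).sum())
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / np.where(poly, sxx, 1.0))
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)
    df = pd.DataFrame({
        "snp_id": list(snp_ids), "beta": beta, "se": se, "z": z, "p": p,
    })
    return df.loc[poly].reset_index(drop=True), excluded


def _gwas_records_from_stats(
    stats_df: pd.DataFrame, panel: HaplotypePanel, genotypes: np.ndarray
) -> list[GwasSnpRecord]:
    freq = np.asarray(genotypes, dtype=float).mean(axis=0) / 2.0
    maf_all = np.minimum(freq, 1.0 - freq)
    meta = panel.snps.set_index("snp_id")
    idx = panel.index_of(stats_df["snp_id"])
    out = []
    for (snp, p), i in zip(stats_df[["snp_id", "p"]].itertuples(index=False), idx):
        row = meta.loc[snp]
        out.append(GwasSnpRecord(
            snp_id=snp, p_value=float(p), chrom=str(row["chrom"]),
            pos=int(row["pos"]), ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]), maf=float(max(maf_all[i], P_FLOOR)),
            info=1.0,
        ))
    return out


def make_null_gwas(
    panel: HaplotypePanel, n: int = 3960, seed: int = 0
) -> list[GwasSnpRecord]:
    """Negative-control GWAS: phenotype drawn N(0,1) independently of
    genotype (a random phenotype reassignment), default n = 3960."""
    G = simulate_cohort(panel, n, seed)
    y = _rng(seed, 3).standard_normal(n)
    stats_df, _ = compute_summary_stats(G, y, panel.snp_ids)
    return _gwas_records_from_stats(stats_df, panel, G)


def simulate_eqtl_dataset(
    panel: HaplotypePanel, scenario: SimScenario, n: int, seed: int
) -> list[EqtlRecord]:
    """An eQTL summary dataset: a fresh cohort of size ``n``, expression per
    the scenario, and per-gene cis regressions (each gene against the SNPs
    of its own block)."""
    G = simulate_cohort(panel, n, seed)
    X, _ = simulate_expression_and_phenotype(G, scenario, seed)
    records: list[EqtlRecord] = []
    for i, gid in enumerate(scenario.gene_ids):
        lo, hi, _rho = panel.blocks[i]
        ids = panel.snp_ids[lo:hi]
        stats_df, _ = compute_summary_stats(G[:, lo:hi], X.iloc[:, i].to_numpy(), ids)
        for row in stats_df.itertuples(index=False):
            records.append(EqtlRecord(snp_id=row.snp_id, gene_id=gid,
                                      p_value=float(row.p), beta=float(row.beta),
                                      cis_flag=True))
    return records


def simulate_study(scenario: SimScenario) -> SummaryStatsBundle:
    """The full discovery-stage input set: panel, gene models, eQTL summary
    statistics (n_eqtl_cohort), GWAS summary statistics from an independent
    cohort (n_gwas_cohort) with the mediated phenotype, and the truth table."""
    panel = make_haplotype_panel(scenario)
    genes = gene_models(scenario)
    eqtl = simulate_eqtl_dataset(panel, scenario, scenario.n_eqtl_cohort,
                                 seed=scenario.seed * 8 + 1)
    G_g = simulate_cohort(panel, scenario.n_gwas_cohort, seed=scenario.seed * 8 + 2)
    _, y = simulate_expression_and_phenotype(G_g, scenario, seed=scenario.seed * 8 + 2)
    stats_df, _ = compute_summary_stats(G_g, y, panel.snp_ids)
    gwas = _gwas_records_from_stats(stats_df, panel, G_g)
    esnp = designated_esnp_index(scenario)
    truth = pd.DataFrame({
        "gene_id": scenario.gene_ids,
        "causal": [g in scenario.causal for g in scenario.gene_ids],
        "esnp_id": [panel.snp_ids[esnp[g]] for g in scenario.gene_ids],
        "eqtl_beta": [scenario.eqtl_effect if g in scenario.eqtl_genes else 0.0
                      for g in scenario.gene_ids],
        "mediation_beta": [scenario.mediation_effect if g in scenario.causal else 0.0
                           for g in scenario.gene_ids],
    })
    return SummaryStatsBundle(gwas=gwas, eqtl=eqtl, genes=genes, truth=truth,
                              panel=panel, scenario=scenario)


def make_expression_groups(
    n_low: int = 10,
    n_high: int = 10,
    de_gene_ids: Iterable[str] = (),
    de_shift: float = 2.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Two-group expression matrix: N(0,1) noise per gene/sample, with
    ``de_shift`` added to ``de_gene_ids`` in the *low* group (up-regulation
    in low-phenotype subjects).  Default group sizes follow the two
    case/control microarray sets emulated here (10v10 and 9v10)."""
    if n_low < 2 or n_high < 2:
        raise ValueError("both groups need >= 2 samples")
    de = list(dict.fromkeys(de_gene_ids))
    if gene_ids is None:
        n_bg = max(36 - len(de), 0)
        gene_ids = de + [f"BG{i + 1:03d}" for i in range(n_bg)]
    gene_ids = list(gene_ids)
    if not set(de) <= set(gene_ids):
        raise ValueError("de_gene_ids must be contained in gene_ids")
    rng = _rng(seed, 4)
    values = rng.standard_normal((len(gene_ids), n_low + n_high))
    de_rows = [gene_ids.index(g) for g in de]
    values[de_rows, :n_low] += de_shift
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"low_{i + 1:02d}" for i in range(n_low)]
        + [f"high_{i + 1:02d}" for i in range(n_high)],
        values=values,
        group=["low"] * n_low + ["high"] * n_high,
    )


def make_gene_sets(
    scenario: SimScenario, n_sets: int = 10, set_size: int = 15, seed: int = 0
):
    """Synthetic GMT-style gene sets over the scenario's gene universe: one
    set containing all causal genes (a 'causal pathway') plus random sets."""
    from .io_formats import GeneSet

    rng = _rng(seed, 5)
    genes = scenario.gene_ids
    causal = sorted(scenario.causal)
    non_causal = [g for g in genes if g not in scenario.causal]
    fill = rng.choice(non_causal, size=max(0, set_size - len(causal)),
                      replace=False)
    sets = [GeneSet("SET_CAUSAL", "pathway containing the causal genes",
                    tuple(causal) + tuple(str(g) for g in sorted(fill)))]
    for i in range(1, n_sets):
        members = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        sets.append(GeneSet(f"SET_{i:02d}", "random gene set",
                            tuple(str(g) for g in sorted(members))))
    return sets


def make_interaction_edges(
    gene_ids: Sequence[str], hub_gene: str, seed: int = 0, n_random: int = 40
):
    """Synthetic undirected interaction edge list with one designated hub:
    the hub is linked to up to 8 other genes, the rest are random pairs with
    random interaction types."""
    from .enrichment_network import EDGE_TYPES, InteractionEdge

    if hub_gene not in gene_ids:
        raise ValueError("hub_gene must be among gene_ids")
    rng = _rng(seed, 6)
    others = [g for g in gene_ids if g != hub_gene]
    edges = {}
    for nbr in rng.choice(others, size=min(8, len(others)), replace=False):
        e = InteractionEdge(hub_gene, str(nbr),
                            str(rng.choice(EDGE_TYPES)), 1.0)
        edges[e.key] = e
    for _ in range(n_random):
        a, b = rng.choice(gene_ids, size=2, replace=False)
        e = InteractionEdge(str(a), str(b), str(rng.choice(EDGE_TYPES)),
                            float(np.round(rng.uniform(0.1, 1.0), 3)))
        edges.setdefault(e.key, e)
    return sorted(edges.values(), key=lambda e: e.key)


# ---------------------------------------------------------------------------
# panel serialization
# ---------------------------------------------------------------------------


def write_panel_tsv(panel: HaplotypePanel, path) -> None:
    """One row per SNP: metadata, block index, block rho, and the haplotype
    column packed as a 0/1 string."""
    block_of = np.empty(panel.n_snps, dtype=int)
    rho_of = np.empty(panel.n_snps, dtype=float)
    for b, (lo, hi, rho) in enumerate(panel.blocks):
        block_of[lo:hi] = b
        rho_of[lo:hi] = rho
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\tblock\trho\thaplotypes\n")
        for i, row in enumerate(panel.snps.itertuples(index=False)):
            hap = "".join(map(str, panel.haplotypes[:, i]))
            fh.write(f"{row.snp_id}\t{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}"
                     f"\t{block_of[i]}\t{float(rho_of[i])!r}\t{hap}\n")


def read_panel_tsv(path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    snps = pd.DataFrame({
        "snp_id": df["snp_id"], "chrom": df["chrom"],
        "pos": df["pos"].astype(int), "ref": df["ref"], "alt": df["alt"],
    })
    hap = np.array([[int(c) for c in s] for s in df["haplotypes"]],
                   dtype=np.uint8).T
    blocks = []
    block_ids = df["block"].astype(int).to_numpy()
    rhos = df["rho"].astype(float).to_numpy()
    for b in np.unique(block_ids):
        where = np.flatnonzero(block_ids == b)
        blocks.append((int(where[0]), int(where[-1] + 1), float(rhos[where[0]])))
    return HaplotypePanel(snps=snps, haplotypes=hap, blocks=blocks)


def read_panel_vcf(path) -> HaplotypePanel:
    """Load a phased VCF as a haplotype panel (block structure unknown; the
    whole file is treated as one block with undefined rho)."""
    from cyvcf2 import VCF

    rows = []
    haps = []
    for var in VCF(str(path)):
        gt = np.asarray([g[:2] for g in var.genotypes], dtype=int).ravel()
        if (gt < 0).any():
            raise ValueError(f"missing genotypes at {var.ID or var.POS}")
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF, var.ALT[0] if var.ALT else "."))
        haps.append(gt)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    hap = np.asarray(haps, dtype=np.uint8).T
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return HaplotypePanel(snps=snps, haplotypes=hap,
                          blocks=[(0, len(rows), float("nan"))])
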