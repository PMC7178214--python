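"""End-to-end orchestration: simulate (or load) inputs, run the discovery
and replication integration stages, the gene-based test on the real and the
null GWAS, overlap permutations, enrichment, hub ranking and differential
expression, and emit a consolidated per-gene evidence report.

Every stage's outputs are plain TSV under the run directory, together with
a JSON manifest (config, seeds, versions) and a plain-text run log; given
the same configuration a re-run reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .bayes_integration import (BayesConfig, GeneIntegrationResult, replicate,
                                results_to_frame as bayes_frame, score_genes)
from .enrichment_network import (enrich_gene_sets, enrichment_to_frame,
                                 load_edges, rank_hubs, write_edges)
from .expression_analysis import (coexpression, coexpression_difference,
                                  dge_to_frame, dge_ttest)
from .gene_based_test import (GeneBasedResult, results_to_frame as gene_frame,
                              run_gene_based, significant_genes)
from .io_formats import (ExpressionMatrix, gene_sets_as_dict, read_eqtl,
                         read_expression, read_gene_sets, read_genes,
                         read_gwas, write_eqtl, write_expression,
                         write_gene_sets, write_genes, write_gwas)
from .overlap_permutation import permutation_overlap
from .synthetic_data import (SimScenario, make_expression_groups,
                             make_gene_sets, make_interaction_edges,
                             make_null_gwas, read_panel_tsv,
                             simulate_eqtl_dataset, simulate_study,
                             write_panel_tsv)

__all__ = ["PipelineConfig", "run_pipeline", "build_report"]

logger = logging.getLogger(__name__)

_TIER_ORDER = {"triple_support": 0, "replicated": 1, "discovery_only": 2}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With no input paths the pipeline simulates everything from
    ``scenario``; any path that is set replaces the corresponding
    simulated input.
    """

    out_dir: str = "convergene_run"
    scenario: SimScenario = field(default_factory=SimScenario)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    window_kb: int = 20
    alpha: float = 0.05
    n_perm: int = 100_000
    genebased_method: str = "auto"
    # stage toggles
    run_replication: bool = True
    run_genetest: bool = True
    run_nullgwas: bool = True
    run_overlap: bool = True
    run_enrichment: bool = True
    run_dge: bool = True
    run_hubs: bool = True
    # optional real inputs
    gwas_path: str | None = None
    eqtl_path: str | None = None
    replication_eqtl_path: str | None = None
    genes_path: str | None = None
    panel_path: str | None = None
    null_gwas_path: str | None = None
    gene_sets_path: str | None = None
    expression_paths: list[tuple[str, str]] = field(default_factory=list)
    edges_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario_kw = dict(raw.pop("scenario", {}) or {})
        for key in ("causal_gene_ids", "eqtl_gene_ids"):
            if scenario_kw.get(key) is not None:
                scenario_kw[key] = frozenset(scenario_kw[key])
        bayes_kw = dict(raw.pop("bayes", {}) or {})
        raw["expression_paths"] = [tuple(p) for p in raw.get("expression_paths", [])]
        return cls(scenario=SimScenario(**scenario_kw),
                   bayes=BayesConfig(**bayes_kw), **raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in dataclasses.asdict(self.scenario).items()
        }
        d["bayes"] = dataclasses.asdict(self.bayes)
        d["version"] = __version__
        return d


def build_report(
    discovery: Iterable[GeneIntegrationResult],
    replication: Iterable[GeneIntegrationResult] | None = None,
    genebased: Iterable[GeneBasedResult] | None = None,
    null_genebased: Iterable[GeneBasedResult] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Consolidated per-gene evidence table.

    Outer join over the union of the stage gene universes; missing evidence
    stays missing (NA), never failure.  ``evidence_tier``:

    * ``triple_support`` — discovery corrected p < alpha AND replication
      raw p < alpha AND gene-based corrected p < alpha AND not significant
      on the null GWAS;
    * ``replicated`` — the first two conditions;
    * ``discovery_only`` — everything else (including missing evidence).
    """
    def keyed(results, stage):
        out = {}
        for r in results:
            if r.gene_id in out:
                raise ValueError(f"duplicate gene_id {r.gene_id!r} in {stage} output")
            out[r.gene_id] = r
        return out

    disc = keyed(discovery, "discovery")
    repl = keyed(replication, "replication") if replication is not None else None
    gb = keyed(genebased, "gene-based") if genebased is not None else None
    nullgb = keyed(null_genebased, "null gene-based") if null_genebased is not None else None

    universe = set(disc)
    for stage in (repl, gb, nullgb):
        if stage is not None:
            universe |= set(stage)

    rows = []
    for gene in sorted(universe):
        d = disc.get(gene)
        r = repl.get(gene) if repl is not None else None
        g = gb.get(gene) if gb is not None else None
        ng = nullgb.get(gene) if nullgb is not None else None
        disc_sig = d is not None and d.p_corrected < alpha
        repl_ok = r is not None and r.p_empirical < alpha
        gb_sig = g is not None and g.p_corrected < alpha
        null_clean = ng is not None and not (ng.p_corrected < alpha)
        if disc_sig and repl_ok and gb_sig and null_clean:
            tier = "triple_support"
        elif disc_sig and repl_ok:
            tier = "replicated"
        else:
            tier = "discovery_only"
        rows.append({
            "gene_id": gene,
            "lbf": d.lbf_total if d else pd.NA,
            "sherlock_discovery_p": d.p_corrected if d else pd.NA,
            "sherlock_replication_p": r.p_empirical if r else pd.NA,
            "genebased_p": g.p_corrected if g else pd.NA,
            "nullgwas_nonsignificant": (not (ng.p_corrected < alpha)) if ng else pd.NA,
            "evidence_tier": tier,
        })
    df = pd.DataFrame(rows)
    df["_tier"] = df["evidence_tier"].map(_TIER_ORDER)
    df["_lbf"] = pd.to_numeric(df["lbf"], errors="coerce").fillna(float("-inf"))
    df = df.sort_values(["_tier", "_lbf", "gene_id"],
                        ascending=[True, False, True])
    return df.drop(columns=["_tier", "_lbf"]).reset_index(drop=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def add(self, line: str) -> None:
        self.lines.append(line)
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run
    directory.  A stage failure aborts the run with the stage named in the
    raised error and a ``FAILED`` marker file; outputs of completed stages
    are retained."""
    out = Path(config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.txt")
    scenario = config.scenario
    seed = scenario.seed
    state: dict = {}

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            log.add(f"stage {name}: FAILED ({exc})")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.add(f"stage {name}: ok (seed={seed})")

    def s_inputs():
        inputs = out / "inputs"
        if config.gwas_path is None:
            bundle = simulate_study(scenario)
            state["panel"] = bundle.panel
            state["gwas"] = bundle.gwas
            state["eqtl"] = bundle.eqtl
            state["genes"] = bundle.genes
            write_gwas(bundle.gwas, inputs / "gwas.tsv")
            write_eqtl(bundle.eqtl, inputs / "eqtl.tsv")
            write_genes(bundle.genes, inputs / "genes.bed")
            write_panel_tsv(bundle.panel, inputs / "panel.tsv")
            bundle.truth.to_csv(inputs / "truth.tsv", sep="\t", index=False)
            if config.run_replication:
                state["eqtl_repl"] = simulate_eqtl_dataset(
                    bundle.panel, scenario, scenario.n_replication_cohort,
                    seed=seed * 8 + 3)
                write_eqtl(state["eqtl_repl"], inputs / "eqtl_replication.tsv")
            if config.run_nullgwas:
                state["null_gwas"] = make_null_gwas(
                    bundle.panel, scenario.n_null_cohort, seed=seed * 8 + 4)
                write_gwas(state["null_gwas"], inputs / "null_gwas.tsv")
        else:
            state["gwas"] = read_gwas(config.gwas_path)
            state["eqtl"] = read_eqtl(config.eqtl_path)
            state["genes"] = read_genes(config.genes_path)
            state["panel"] = read_panel_tsv(config.panel_path)
            if config.run_replication:
                state["eqtl_repl"] = read_eqtl(config.replication_eqtl_path)
            if config.run_nullgwas:
                state["null_gwas"] = read_gwas(config.null_gwas_path)

    def s_discovery():
        state["discovery"] = score_genes(state["eqtl"], state["gwas"],
                                         state["panel"], config.bayes, seed=seed)
        _write_tsv(bayes_frame(state["discovery"]), out / "sherlock_discovery.tsv")

    def s_replication():
        state["replication"] = score_genes(state["eqtl_repl"], state["gwas"],
                                           state["panel"], config.bayes, seed=seed)
        _write_tsv(bayes_frame(state["replication"]),
                   out / "sherlock_replication.tsv")
        _write_tsv(replicate(state["discovery"], state["replication"],
                             config.alpha),
                   out / "replication_join.tsv")

    def s_genetest():
        state["genebased"] = run_gene_based(
            state["gwas"], state["genes"], state["panel"],
            window_kb=config.window_kb, alpha=config.alpha,
            method=config.genebased_method, seed=seed)
        _write_tsv(gene_frame(state["genebased"]), out / "genetest_gwas.tsv")

    def s_nullgwas():
        state["null_genebased"] = run_gene_based(
            state["null_gwas"], state["genes"], state["panel"],
            window_kb=config.window_kb, alpha=config.alpha,
            method=config.genebased_method, seed=seed)
        _write_tsv(gene_frame(state["null_genebased"]), out / "genetest_null.tsv")

    def s_overlap():
        background = {r.gene_id for r in state["discovery"]}
        for key in ("replication", "genebased"):
            if key in state:
                background |= {r.gene_id for r in state[key]}
        query = {r.gene_id for r in state["discovery"]
                 if r.p_corrected < config.alpha}
        rows = []
        if "replication" in state:
            ref = {r.gene_id for r in state["replication"]
                   if r.p_empirical < config.alpha}
            res = permutation_overlap(background, query, ref,
                                      n_perm=config.n_perm, seed=seed)
            rows.append({"comparison": "replication_suggestive",
                         **dataclasses.asdict(res)})
        if "genebased" in state:
            ref = significant_genes(state["genebased"], config.alpha)
            res = permutation_overlap(background, query, ref,
                                      n_perm=config.n_perm, seed=seed)
            rows.append({"comparison": "genebased_significant",
                         **dataclasses.asdict(res)})
        _write_tsv(pd.DataFrame(rows), out / "overlap.tsv")

    def s_enrichment():
        if config.gene_sets_path is not None:
            sets = read_gene_sets(config.gene_sets_path)
        else:
            sets = make_gene_sets(scenario, seed=seed)
            write_gene_sets(sets, out / "inputs" / "sets.gmt")
        background = {r.gene_id for r in state["discovery"]}
        query = {r.gene_id for r in state["discovery"]
                 if r.p_corrected < config.alpha}
        results = enrich_gene_sets(query, gene_sets_as_dict(sets), background,
                                   alpha=config.alpha,
                                   descriptions={s.set_id: s.description
                                                 for s in sets})
        _write_tsv(enrichment_to_frame(results), out / "enrichment.tsv")

    def s_dge():
        if config.expression_paths:
            matrices = [read_expression(e, g) for e, g in config.expression_paths]
            names = [f"expr{i + 1}" for i in range(len(matrices))]
        else:
            de = sorted(scenario.causal)
            matrices = [
                make_expression_groups(10, 10, de, seed=seed),
                make_expression_groups(9, 10, de, seed=seed + 1),
            ]
            names = ["expr_gse2208like", "expr_gse7429like"]
            for m, name in zip(matrices, names):
                write_expression(m, out / "inputs" / f"{name}.tsv",
                                 out / "inputs" / f"{name}_groups.tsv")
        for m, name in zip(matrices, names):
            _write_tsv(dge_to_frame(dge_ttest(m, alpha=config.alpha)),
                       out / f"dge_{name}.tsv")
        first = matrices[0]
        corr_low = coexpression(first, "low")
        corr_high = coexpression(first, "high")
        diff = coexpression_difference(corr_low, corr_high)
        corr_low.to_csv(out / "corr_low.tsv", sep="\t")
        corr_high.to_csv(out / "corr_high.tsv", sep="\t")
        diff.diff.to_csv(out / "corr_diff.tsv", sep="\t")

    def s_hubs():
        query = sorted({r.gene_id for r in state["discovery"]
                        if r.p_corrected < config.alpha} | scenario.causal)
        if config.edges_path is not None:
            edges = load_edges(config.edges_path)
        else:
            hub = sorted(scenario.causal)[0]
            edges = make_interaction_edges(query, hub, seed=seed)
            write_edges(edges, out / "inputs" / "edges.tsv")
        _write_tsv(rank_hubs(edges, query), out / "hubs.tsv")

    def s_report():
        df = build_report(state["discovery"], state.get("replication"),
                          state.get("genebased"), state.get("null_genebased"),
                          alpha=config.alpha)
        _write_tsv(df, out / "report.tsv")
        state["report"] = df

    stage("inputs", s_inputs)
    stage("sherlock_discovery", s_discovery)
    if config.run_replication:
        stage("sherlock_replication", s_replication)
    if config.run_genetest:
        stage("genetest", s_genetest)
    if config.run_nullgwas:
        stage("genetest_null", s_nullgwas)
    if config.run_overlap:
        stage("overlap", s_overlap)
    if config.run_enrichment:
        stage("enrichment", s_enrichment)
    if config.run_dge:
        stage("dge", s_dge)
    if config.run_hubs:
        stage("hubs", s_hubs)
    stage("report", s_report)

    manifest = config.to_manifest()
    manifest["stages_run"] = [l.split(":")[0].removeprefix("stage ")
                              for l in log.lines]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    log.add("pipeline: complete")
    return out
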