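# convergene

Convergent prioritization of trait risk genes from summary statistics.
`convergene` re-implements, as a tested and reusable pipeline, an
integrative-genomics analysis for quantitative traits such as bone mineral
density: genes are scored by Bayesian integration of eQTL and GWAS summary
statistics, validated with an LD-aware gene-based association test and a
null-GWAS negative control, and corroborated with permutation overlap
statistics, gene-set enrichment, interaction-network hub ranking, and
case/control differential-expression analysis.  A first-class synthetic-data
module generates inputs with the statistical structure the analysis assumes
(LD-blocked haplotypes, cis-eQTL effects, an expression-mediated phenotype),
so every stage is testable end to end without any downloads.

It is intended for statistical geneticists and methodologists who want a
transparent, fully specified desk-scale version of this class of analysis.

## The statistics at the core

**Per-gene log Bayes factor.**  For each gene, expression-associated SNPs
(eSNPs: eQTL p < τₑ, default 10⁻⁵) are LD-pruned (greedy, r² > 0.2 against a
reference haplotype panel) and each retained eSNP's GWAS evidence is scored
with a Wakefield-style normal-mixture log₁₀ Bayes factor on the z scale,

    z   = Φ⁻¹(1 − p/2)
    LBF = log₁₀ [ N(z; 0, 1+W) / N(z; 0, 1) ]
        = ½ log₁₀ 1/(1+W) + (z²/2) · W/(1+W) · log₁₀ e ,      W = 4 by default.

The score is positive for strong GWAS signals, negative near z = 0, and SNPs
that are not eSNPs contribute nothing.  A gene's score is the sum over its
pruned eSNPs; its significance is empirical, from Monte-Carlo draws of the
null sum (iid standard-normal z's, add-one estimator, Bonferroni-corrected
over genes tested).

**LD-aware gene-based test.**  SNPs map to genes with ±20 kb windows; the
gene statistic is T = Σⱼ zⱼ², whose null is the eigenvalue-weighted mixture
Σₖ λₖ χ²₁ with λ the eigenvalues of the SNPs' panel LD matrix.  The tail is
computed essentially exactly (χ² for one eigenvalue, a conditioning integral
for two, Imhof's characteristic-function inversion for three or more), with
Satterthwaite and Monte-Carlo methods available explicitly.

**Overlap, enrichment, expression.**  Overlap between gene lists is tested
by drawing |query| genes from the background 100,000 times (with the exact
hypergeometric tail computed alongside as an oracle); gene sets are tested
with the two-sided hypergeometric test and Holm ("Bonferroni step-down")
correction; expression differences use the pooled-variance Student t-test
with per-group Pearson co-expression matrices and their difference.

## Worked example

Score a simulated study (200 genes, 5 causal, monocyte-scale eQTL cohort of
1490, GWAS cohort of 5000):

```python
from convergene import SimScenario, simulate_study, score_genes, BayesConfig
from convergene.bayes_integration import results_to_frame

scenario = SimScenario(seed=1)           # 200 genes; G0001..G0005 causal
bundle = simulate_study(scenario)
results = score_genes(bundle.eqtl, bundle.gwas, bundle.panel,
                      BayesConfig(), seed=1)
table = results_to_frame(results).sort_values("lbf", ascending=False)
print(table.head(8).to_string(index=False))
```

prints

```
gene_id  n_esnps      lbf  p_empirical  p_corrected
  G0003        1 8.457353 9.999990e-07       0.0002
  G0004        3 6.723164 9.999990e-07       0.0002
  G0002        2 6.510640 9.999990e-07       0.0002
  G0005        2 3.885237 3.999996e-06       0.0008
  G0172        2 1.935738 5.069995e-04       0.1014
  G0121        1 1.864561 3.469997e-04       0.0694
  G0001        2 1.761752 8.479992e-04       0.1696
  G0104        2 1.677543 1.069999e-03       0.2140
```

All five causal genes sit in the top seven of 200 by summed LBF; the four
strongest reach Bonferroni-corrected empirical p ≤ 8×10⁻⁴ (the floor
10⁻⁶ × 200 reflects the 10⁶-draw null).  The independent gene-based test
concurs — its top four genes are G0003, G0002, G0004, G0005 with corrected
p from 7.6×10⁻⁵ to 6.5×10⁻³ — while the same test run on a null GWAS
(randomly drawn phenotype, n = 3960) flags nothing.

The same stages are available from the shell:

```bash
convergene simulate --out run/
convergene sherlock --gwas run/inputs/gwas.tsv --eqtl run/inputs/eqtl.tsv \
    --panel run/inputs/panel.tsv --out sherlock.tsv
convergene run --config run.yaml        # the full orchestrated pipeline
```

## Layout

* `src/convergene/io_formats.py` — TSV/BED/GMT/expression readers & writers,
  SNP quality filters (GWAS: MAF ≥ 0.1%, info > 0.4; genotypes: HWE > 10⁻⁴,
  call rate > 98%, MAF > 1%).
* `src/convergene/synthetic_data.py` — haplotype panel, cohorts, expression,
  phenotype, summary statistics, null GWAS, two-group expression matrices.
* `src/convergene/bayes_integration.py` — eSNP detection, LBF scoring,
  empirical null, discovery/replication joining.
* `src/convergene/gene_based_test.py` — SNP→gene windows, LD matrices,
  weighted-χ² gene test.
* `src/convergene/overlap_permutation.py` — permutation overlap statistics.
* `src/convergene/enrichment_network.py` — hypergeometric enrichment (Holm),
  hub ranking on interaction edge lists.
* `src/convergene/expression_analysis.py` — two-group t-tests,
  co-expression difference.
* `src/convergene/pipeline.py`, `cli.py` — orchestration and the
  `convergene` command.

See `docs/methods.md` for the model, parameter and calibration details.
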