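# agesel

Tools for asking how the age at which a gene is expressed shapes its
molecular evolution.  Genes expressed late in life sit in the "selection
shadow": purifying selection against their deleterious variants is weaker,
so late-expressed genes are expected to carry more nonsynonymous
polymorphism, fix nonsynonymous changes faster, and be lost from genomes
sooner.  `agesel` implements the statistics and models needed to test those
predictions on gene-level tabular data, together with a synthetic cohort
generator that plants the assumed structure so every stage of the pipeline
can be validated against known truth.

The package is aimed at population geneticists and molecular evolution
researchers working with per-gene summaries (segregating-site counts, dN/dS,
gene ages) joined to expression time courses over organismal age.

## What it computes

**Age of expression.**  For each gene, REA — the ordinary least-squares slope
of log expression on sample age.  Positive REA = expressed most strongly late
in life.  Also: the age of maximum expression, the tissue-specificity index
τ = Σᵢ(1 − xᵢ/x_max)/(N−1), early/late classes from the 10th/90th REA
percentiles, and the proportional early-vs-late contrast in dN/dS,

    ΔR_NS = [(dN/dS)_late − (dN/dS)_early] / (½[(dN/dS)_late + (dN/dS)_early]),

which is bounded in [−2, 2].

**Selection inference (Poisson random field).**  Each gene's nonsynonymous
mutations are beneficial with probability α_m (scaled effect +Nₑs as
homozygotes) and deleterious otherwise (−Nₑs); synonymous mutations are
neutral; sites evolve independently.  The expected polymorphic and fixed
site counts are diffusion integrals over the allele-frequency sojourn
density — e.g. the synonymous expectation in a sample of m copies is
4NₑμS·H_{m−1} — and pN/pS and dN/dS follow as ratios that depend only on
(Nₑs, α_m, μN/μS, m).  `prf_inference` inverts the forward model: with
μN/μS fixed at the gene's site-count ratio, the observed (pN/pS, dN/dS)
pin down (N̂ₑs, α̂_m) numerically.  A discrete Wright–Fisher simulator serves
as an independent oracle for the forward predictions.

**Gene lifespan.**  Fixations move a gene's fitness up (probability α) or
down by s; the gene is lost when k more deleterious than beneficial changes
have fixed.  This gambler's-ruin walk gives the expected number of
substitutions before loss, n̄_T = k/(1−2α) for α < ½, and the expected time
to loss t̄ ≈ (k/(r_B+r_D))(1 + 2r_B/(r_B+r_D)) at fixation rates r_B, r_D —
so genes under weaker purifying selection (larger r_D) die younger.

**Association layer.**  yᵢ = b₀ + b₁·REAᵢ + b₂·mean_exprᵢ + eᵢ with τ and
fixed per-tissue intercepts as additional covariates where available;
significance via two-sided Spearman rank correlation (uncorrected), Wilcoxon
rank-sum tests and binned enrichment curves for binary gene lists, and
within-pair paralog contrasts (Δstatistic regressed on ΔREA).

## Worked example

```bash
agesel simulate --seed 42 --outdir demo           # 2000-gene synthetic cohort
agesel metrics --expression demo/expression.tsv --samples demo/samples.tsv \
               --genes demo/genes.tsv --out demo/genes_metrics.tsv
agesel prf-fit --genes demo/genes_metrics.tsv --m 40 --out demo/genes_fitted.tsv
agesel associate --genes demo/genes_fitted.tsv --response ne_s_hat --out demo/assoc.tsv
```

The same pipeline as a scripted narrative lives in `analysis/01...05`.  On
the seed-42 cohort (planted maps Nₑs = exp(0.5 − 0.5·REA), α_m =
logistic(−2 + REA)) it prints:

```
REA classes: 200 early (<= -1.388), 200 late (>= 1.261)
early/late dN/dS contrast (proportional difference): +1.3534
recovery Spearman rho(ne_s_hat, truth_ne_s) = +0.645
    ne_s_hat: b1=-0.8261  rho=-0.632  p=7.16e-224  (n=2000)
       pn_ps: b1=+0.1547  rho=+0.893  p=0.00e+00   (n=2000)
    gene_age: b1=-9.298   rho=-0.367  p=9.39e-65   (n=2000)
```

Late genes show elevated dN/dS (ΔR_NS = +1.35), the estimated selection
strength declines with REA (ρ = −0.63: the planted a₁ < 0 is recovered in
sign), nonsynonymous polymorphism rises with REA, and late genes are younger
— the full qualitative pattern the selection-shadow hypothesis predicts.

## File formats

TSV with a header, UTF-8, `NA` for missing: `expression.tsv` (genes ×
samples, first column `gene_id`), `samples.tsv` (per-sample `age`, optional
`tissue`/`sex`), `genes.tsv` (`gene_id`, `poly_N`, `poly_S`, `sites_N`,
`sites_S` + free extra columns), `paralogs.tsv` (`gene_a`, `gene_b` plus
`_a`/`_b` statistic columns), `annotation.txt` (one gene id per line, `#`
comments).  Simulation configs are YAML files of `CohortConfig` fields.

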