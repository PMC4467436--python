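# coexsig

Seed-gene coexpression signatures for tumor subtyping, with single-sample
enrichment scoring and treatment-interaction survival analysis.

## The problem

Glioblastoma (GBM) tumors fall into transcriptional subtypes — Proneural
(PN) and Mesenchymal (MES) being the most distinct — and accumulating
evidence ties the stem-cell surface markers CD133 (*PROM1*) and CD44 to
those subtypes. `coexsig` implements a *targeted* coexpression analysis
around such marker genes: instead of building a full gene-gene network, it
asks which genes track a chosen seed marker across a tumor cohort, turns
those genes into a signature, scores every tumor against competing
signatures, and asks whether the resulting dichotomous classification
(e.g. CD133-module vs CD44-module) carries clinical information — in
particular, whether the benefit of radiotherapy or temozolomide differs
between the two classes.

The package is aimed at computational biologists analysing bulk expression
cohorts (TCGA-style log2 matrices) with survival and mutation annotations,
and ships a synthetic-cohort generator that plants every piece of structure
the analysis assumes, so the whole pipeline is testable against known truth.

## Methods at a glance

* **Module discovery** — per-gene Pearson (or Spearman) correlation *r* with
  a seed marker over pairwise-complete samples; two-sided p from
  `t = r sqrt((n-2)/(1-r^2))` on `n-2` df; Benjamini–Hochberg q. Module
  members are the genes with `r > mean(r) + 2 sd(r)`, `q < 0.05`, `r > 0`.
* **Single-sample scoring** — GSVA-style statistic: per-gene empirical-CDF
  transform, genes ranked within each sample, symmetric rank weight
  `|N/2 - rho|`, and a Kolmogorov–Smirnov random walk whose enrichment score
  is `ES = D+ + D-` (the signed difference of the largest positive and
  negative walk deviations). Samples are labelled by the argmax ES over
  candidate modules.
* **Preranked GSEA** — classic weighted KS walk on a correlation-ranked
  gene list, gene-set permutation null, NES, add-one nominal p, pooled
  null-ratio FDR.
* **Inference toolkit** — Wilcoxon rank-sum (exact for pooled n ≤ 12),
  upper-tail hypergeometric overlap (log-space, stable far below 1e-100),
  minimum-likelihood two-sided binomial and Fisher exact tests (with both
  the sample and conditional-MLE odds ratio), Welch t, BH-FDR — all
  implemented from their definitions and cross-checked against independent
  oracles.
* **Survival** — Kaplan–Meier with Greenwood SEs, k-group log-rank, and a
  Cox proportional-hazards fit maximising the Efron-tie partial likelihood
  by damped Newton–Raphson, with per-subtype treatment hazard ratios and
  predicted curves at covariate means.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 1200-gene × 300-sample cohort with two mutually exclusive marker
programs (a CD133-like program active in subtype A, a CD44-like program in
subtype B), a radiotherapy benefit (log HR −1.25) confined to subtype A, and
an IDH1-like mutation enriched in subtype A — then run the full analysis:

```sh
coexsig simulate --out sim --seed 7
cat > config.yaml <<EOF
expression: sim/expression.tsv
clinical: sim/clinical.tsv
mutations: sim/mutations.tsv
markers: [PROM1, CD44]
rng_seed: 7
output_dir: out
EOF
coexsig run-all --config config.yaml
```

`out/report.json` then shows the discovered modules and subtype split:

```
modules:       {"PROM1": 41, "CD44": 38}
label_counts:  {"PROM1": 163, "CD44": 137}
```

i.e. the 2-SD + FDR cutoff recovered 41- and 38-gene modules around the two
markers (50 planted members each), and the argmax-ES classifier split the
300 samples 163/137. `out/associations.tsv` confirms the planted mutation
enrichment in the PROM1-module class:

```
test             item  statistic  effect   or_cmle  p            q
fisher_mutation  IDH1  60         15.3786  15.2601  1.73e-13     1.73e-13
```

and `out/treatment_hr.tsv` is the per-subtype Cox treatment report (age,
G-CIMP, radiotherapy and temozolomide fitted jointly within each stratum):

```
subtype  treatment     hr      ci_low  ci_high  p       n    n_events
CD44     radiotherapy  1.0104  0.6981  1.4625   0.9561  137  120
CD44     temozolomide  0.8803  0.6076  1.2756   0.5006  137  120
PROM1    radiotherapy  0.2985  0.2006  0.4442   1.4e-9  163  120
PROM1    temozolomide  1.1964  0.8266  1.7318   0.3418  163  120
```

The planted interaction is recovered: radiotherapy shows a strong benefit in
the PROM1-module stratum (HR 0.30, true value e^-1.25 ≈ 0.29) and none in
the CD44-module stratum (CI spans 1).

The same stages are available individually (`discover`, `score`, `classify`,
`associate`, `gsea`, `survival`) and as library functions under
`coexsig.pipeline`; every stage writes reloadable TSVs plus a manifest with
input checksums, and a rerun with the same config is byte-identical.

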