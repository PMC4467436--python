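# Methods

This note records the statistical models implemented in `coexsig`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Seed-gene coexpression modules

For a seed marker gene *s* and every other gene *g* in a log-scale
expression matrix, the correlation profile holds Pearson's *r* over
pairwise-complete samples (Spearman = Pearson on average ranks of the same
subset), the two-sided p-value from `t = r sqrt((n_used - 2)/(1 - r^2))` on
`n_used - 2` degrees of freedom, and the Benjamini–Hochberg q over all
finite p of the profile. Genes with fewer than 3 complete pairs or zero
variance are flagged undefined and excluded from every downstream summary.

Module selection applies two filters jointly: `r` must exceed the profile
mean plus `sd_mult` (default 2) standard deviations — mean and SD taken over
the *signed* finite correlations, seed excluded, so an abundance of negative
correlations lowers the bar symmetrically — and `q < fdr_max` (default
0.05), restricted to positive correlations by default because a signature
gene must be co-detected with the marker to be usable. The empirical
percentile of the threshold within the profile is reported so the selection
can be compared with a "top x%" description of the same rule; the SD rule is
the operational definition. The seed never belongs to its own module (its
self-correlation of 1 would distort set statistics). An empty module is a
legal, logged outcome, not an error. FDR correction is per marker profile,
not pooled across markers.

## Single-sample enrichment scores

Scoring follows the GSVA recipe with the empirical-CDF expression statistic:

1. `z_gj = #\{j' : x_gj' <= x_gj\} / n_samples` per gene (ties share a value;
   a constant gene maps to all ones and is uninformative; missing values are
   treated as that gene's lowest expression, keeping per-sample rankings
   total).
2. Within each sample, genes are ordered by decreasing `z` (ties broken by
   gene order, which the pipeline keeps deterministic), and the gene at rank
   `rho` receives walk weight `|N/2 - rho|` — mid-ranked genes contribute
   least, both extremes most.
3. A KS random walk over that ordering adds `w^tau / sum_members w^tau` at
   members (tau default 1, linear weighting) and subtracts `1/(N - m)` at
   non-members. With `D+` the largest positive and `D-` the largest negative
   deviation, the default enrichment score is `ES = D+ + D-`, which rewards
   sets concordantly shifted toward one end of the profile; the classic
   largest-|deviation| score is available as `es_mode="max"`.

The empirical CDF was chosen over a Gaussian-kernel CDF because it is
deterministic, bandwidth-free and rank-equivalent for continuous data; the
kernel variant is a stated extension point, not implemented. ES depends only
on within-gene ranks, so any monotone per-gene transform of the input leaves
scores unchanged (tested).

Subtype calls take the argmax ES over an ordered candidate list; the margin
(winner minus runner-up) is reported and an exact tie falls to the
first-listed candidate with a logged warning — ties are measure-zero for
continuous scores, so one usually signals degenerate input.

## Preranked gene-set enrichment

The preranked walk uses the classic weighted convention: hits add
`|score|^w / sum_hits |score|^w` (w default 1), misses subtract
`1/(N - N_hits)`, and ES is the walk deviation of largest magnitude
(signed). Significance comes from gene-set permutation: ES of `n_perm`
uniformly random same-size sets (seeded; shared across observed sets of
equal matched size). NES divides ES by the mean |null ES| of matching sign;
the nominal p uses the add-one convention `(1 + #extreme)/(1 + #same-sign)`,
so it is never zero; the FDR q is the pooled null-ratio estimate of the
original GSEA procedure, clipped to [0, 1] and monotonised so a more extreme
|NES| never carries a larger q. Set-size filters default to 15–500 matched
genes, the conventional preranked defaults.

## Association tests

All tests are implemented from their definitions; scipy supplies only
`gammaln`/`logsumexp`/distribution tails. Conventions that affect printed
p-values:

* Rank-sum: exact enumeration of all `C(n, nx)` rank assignments when the
  pooled sample is at most 12 with no ties; otherwise the normal
  approximation with tie-corrected variance and continuity correction.
* Binomial and Fisher two-sided p-values use the minimum-likelihood tail
  (sum of outcomes no more probable than the observed one), matching
  standard statistical software; a relative slack of 1e-7 guards tied point
  probabilities against floating-point rounding.
* Fisher's effect is reported both as the sample odds ratio `ad/bc` and the
  conditional-MLE odds ratio (the noncentral-hypergeometric estimate R
  reports), because the two can differ materially in small tables.
* All hypergeometric/binomial mass functions are evaluated in log space and
  tail-summed with `logsumexp`, keeping overlap p-values of order 1e-100 and
  below exact to machine precision.
* BH-FDR is the step-up `q_(i) = min_{j>=i} min(1, p_(j) m / j)`, returned
  in input order; NaN p-values pass through and do not count toward m.

## Survival analysis

Kaplan–Meier is the product-limit estimator with Greenwood standard errors;
subjects censored exactly at an event time count as at risk for that time.
The log-rank test accumulates observed-minus-expected events with the
hypergeometric variance/covariance at each event time and refers the
quadratic form of k−1 groups to chi-square.

The Cox model maximises the Efron-tied partial likelihood — appropriate for
clinical cohorts whose survival times are recorded in whole days and tie
heavily — by Newton–Raphson with step-halving whenever a step would decrease
the likelihood. Covariates are centred at their means, which both stabilises
the optimisation and makes the Breslow baseline curve the prediction for a
mean-covariate profile. Convergence requires the relative log-likelihood
change to fall below 1e-9 *and* the last Newton step below 1e-7 in every
coordinate (the second condition pins the optimum well below the noise floor
of reference implementations); the iteration cap is 50 and non-convergence
is flagged, never silent. A coefficient beyond |beta| > 15 flags monotone-
likelihood divergence (e.g. perfect separation). Wald 95% CIs come from the
observed information. Rows with missing covariates are dropped with a logged
count; a constant covariate is an error naming the covariate.

Predicted curves use `S(t|x) = S0(t)^exp(beta . (x - xbar))` with the
Breslow baseline; omitted covariates sit at the dataset mean, so an empty
profile reproduces the baseline curve exactly.

The treatment-interaction analysis fits one joint Cox model (age, G-CIMP,
radiotherapy, temozolomide) *within each subtype stratum* and tabulates the
treatment rows. The joint-model reading was preferred over separate
per-treatment models because the treatments are assigned independently and
the joint fit adjusts each for the other; per-treatment models can be run by
passing a reduced covariate list. Strata with fewer than 10 events carry a
`few-events` flag.

## Synthetic cohorts

The generator plants exactly the structure the pipeline assumes:

* **Expression** — member gene g of module m in sample j is
  `x = baseline + noise_sd (a_mj + sqrt(rho) f_mj + sqrt(1-rho) e_gj)` with
  `f` a shared unit-variance latent factor, `e` iid standard normal, and
  `a_mj` the subtype activation (in member-gene SD units) of sample j's
  subtype. The sqrt-rho mixing makes the within-subtype member–member and
  member–seed correlation exactly `latent_corr`; with zero activation the
  cohort-level correlation equals `latent_corr` too. The activation enters
  in gene-SD units rather than as a shift of the factor because the factor
  realisation is the dominant per-sample noise of any module score: a
  factor-unit shift of size `a` caps two-program classification accuracy at
  `Phi(a/sqrt(2))` regardless of `latent_corr`, whereas the gene-unit
  parameterisation leaves subtype separation and member correlation
  independently tunable.
* **Defaults** (`two_program_config`): 1200 genes, 300 samples, two 50-gene
  programs with a ±0.5 SD activation split (1 SD total separation), and a
  within-subtype `latent_corr` of 0.05. The small residual correlation
  encodes the view that bulk-tumor module coexpression is dominated by the
  subtype effect itself; combined with the activation it yields cohort-level
  module correlations near 0.25, typical of marker coexpression modules, and
  a classifier accuracy around 0.99.
* **Clinical** — exponential event times with hazard
  `baseline_hazard * exp(sum of treatment log-HRs for the sample's subtype)`,
  treatments Bernoulli(0.5), independent exponential censoring capped at an
  accrual horizon; times in days (default baseline hazard 1/400 per day,
  censoring 1/2000 per day, horizon 10 years). Age ~ Normal(58, 10); the
  G-CIMP flag has probability 0.4 in the designated subtype vs 0.05
  elsewhere.
* **Mutations** — independent Bernoulli per (gene, sample) with
  subtype-conditional probabilities.
* **Seeding** — one integer seed; each sub-generator (subtype assignment,
  expression, clinical, mutation) draws from its own named substream, so
  adding a generator never perturbs the others and all outputs are
  bit-reproducible.

What the generator does **not** emulate: heavy-tailed or platform-specific
expression distributions, batch effects, probe-level structure, correlated
mutations, informative censoring, or more than one latent program per gene.
Passing tests therefore demonstrate correctness of the algorithms under the
stated model, not robustness to every artefact of real cohorts.

## Numerical conventions and degenerate inputs

* Gene identifiers are matched case-sensitively after whitespace trimming.
* Rank ties: average ranks (Spearman, rank-sum); per-sample score ordering
  ties broken by gene order; ranked-list ties broken by gene id.
* Empty module: legal with warning. Set matching < 2 genes: skipped with
  warning; no scorable set: error. All-censored survival input: flat KM
  curve with warning. Zero-margin 2×2 table: p = 1, odds ratio undefined.
* All file output is UTF-8 with LF endings; write→read round trips are
  lossless to at least 6 significant digits (10 are written).

## Known limitations

* The Gaussian-kernel CDF variant of the expression statistic is not
  implemented; for heavily tied count data the ECDF transform is coarse.
* Phenotype-permutation GSEA is out of scope (gene-set permutation only).
* No time-varying covariates, frailty or competing risks in the Cox model.
* The conditional-MLE odds ratio is located by solving the mean equation to
  1e-12 on the log scale; at the support boundary it is reported as 0 or
  infinity rather than estimated.
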