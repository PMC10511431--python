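# Methods

This note documents the statistical machinery, the synthetic study
conditions, the numerical choices, and what the passing tests do and do
not establish.

## Correlation screening

Association between the query gene and every other expressed gene is
Spearman's ρ: Pearson correlation on mid-ranks (average ranks for ties),
computed on pairwise-complete observations; a context is skipped below 3
complete pairs, and a gene with zero rank variance in context is recorded
as missing and kept out of the multiple-testing family. Two-sided
p-values use the t-approximation t = ρ√((n−2)/(1−ρ²)) for n > 8 and the
fully enumerated permutation null for n ≤ 8 (8! = 40 320 pairings,
vectorized). Enumeration at n = 9–10 would cost 3.6 M permutations per
gene for a negligible accuracy gain over the t-approximation, so 8 is
where the exact path ends. Benjamini–Hochberg correction
(statsmodels) is applied within one (cancer type × stratum) context,
matching the per-context families of the screening design.

The expressed-gene filter keeps genes with mean > 0.5 **and** sample
SD > 0.2 (strict) in at least one cancer type, on the log10(FPKM+1)
scale; the query gene is force-retained with a warning if it fails. The
significance screen is the |ρ| ≥ 0.6 threshold alone — q-values are
reported alongside, and a flag can additionally require q < 0.05 — because
at cohort sample sizes every correlation past 0.6 is overwhelmingly
significant, making the threshold the binding rule.

## Pre-ranked geneset enrichment

The enrichment score is the signed extremum of a weighted KS running sum
over the ranked list: hits advance by |score|^p normalized over in-set
hits (weight exponent p = 1 by default, configurable; p = 0 gives the
classic unweighted statistic), misses retreat by 1/(N − |S|). The null is
built from size-preserving random memberships (gene-label permutation) —
the phenotype was already consumed when the list was ranked, so sample
permutation is not available. NES divides ES by the mean |ES| of
same-signed permutations; the nominal p is the same-signed tail with
add-one smoothing (no p = 0); the FDR is the ratio-of-tails estimate
computed separately for positive and negative NES and capped at 1.
Permutation nulls are cached per set size within a call, so identically
sized sets at a fixed seed share a null — a determinism aid, not a
statistical shortcut (the null depends on membership only through size).
The pan-cancer reporting rule (q < 0.001 and |NES| > 2.3 in ≥ 1 context,
all contexts retained for reported sets) is deliberately strict and fully
configurable.

## TP53 stratification and deltas

Mutation calls are collapsed per sample: any non-silent variant or
homozygous deletion ⇒ MUT; functional class by severity precedence
Truncating/HomDel (nonsense, frameshift, splice, homdel) over
Inframe/Missense (missense, in-frame indel). The mapping is a declared,
configurable default — the grouping scheme of the motivating analysis is
not public in detail. Samples of unknown class stay in ALL but never in a
stratum.

Deltas are oriented MUT − WT, for both per-gene Δρ and per-geneset ΔNES;
antisymmetry is exact by construction and regression-tested. Stratified
analyses are gated on > 20 patients per status (strict '>'; an inclusive
'≥' is available since the motivating description uses both phrasings).
The ΔNES rule keeps two thresholds: 0.6 for significance and 2.3 for
figure-grade reporting.

## Survival

Expression is dichotomized at the within-context sample median, ties to
low. The Cox engine maximizes the partial likelihood by Newton–Raphson
with step-halving (tolerance 1e−9 on the log-likelihood, 50 iterations),
with Efron's tie correction by default and Breslow available; they agree
to 1e−8 without ties (tested). Wald CIs and p-values come from the
observed information. Complete separation or non-convergence yields a
*flagged* fit with missing HR, never an exception; a condition-number
guard (10^10, on standardized covariates) rejects collinear designs. The
engine is cross-checked against lifelines to 1e−6 on coefficients and
standard errors, and against the closed-form exponential rate-ratio MLE
on two-group data. KM curves and the log-rank test delegate to lifelines.

The screen fits every (cancer type × TP53 stratum × {uni, multi}) cell:
univariate needs ≥ 10 events; multivariate additionally needs ≥ 3 of the
4 covariates (tumor size, nodal status, metastasis — ordinal codes — and
AURKA log-expression, entered continuous) observed in ≥ 20 patients, and
then fits complete cases on all four, dropping any covariate entirely
missing in context. Ineligible cells are blanks, not zeros.

## Second-order analysis and consensus clustering

Each gene's per-cancer ρ vector is correlated (Spearman by default,
Pearson optional) with the per-cancer univariate hazard ratios over
pairwise-complete contexts, minimum 3; HRs enter as printed (log-HR
optional — Spearman makes the choice immaterial). The histogram and the
counts beyond ±0.5 are exported. With few contexts the per-gene extremes
are chance-dominated; the analysis driver therefore reports module-level
medians as the meaningful summary.

Cancer types are clustered on their correlation profiles by consensus
K-means: repeated 80% item subsampling (no feature subsampling), K-means
with k-means++ and 10 restarts per draw, consensus entry = co-clustered /
co-sampled. k is a candidate when its consensus-CDF delta-area (area for
k = 2, relative increase afterwards) exceeds the elbow threshold (0.025);
among candidates, k must also be *crisp* — at most 10% of off-diagonal
consensus entries in (0.1, 0.9), the PAC criterion — and the largest
crisp candidate wins (literal delta-area rule as fallback). The PAC
filter exists because forcing extra clusters onto isotropic within-cluster
noise splits items arbitrarily across runs, which keeps inflating the CDF
area past the true k; it cannot, however, reject an over-split that is
*stable* for a particular realized dataset (small fixed clouds admit
these), so the delta-area/PAC table is always exported for inspection,
and k must stay below the subsample size. Final assignments come from
average-linkage clustering of 1 − consensus.

## Pharmacogenomic screen

Engineered and fibroblast lines are dropped, then cancer types with fewer
than two remaining lines. Per (compound, cancer type), eligibility is
evaluated on lines with an observed AUC: ≥ 10 tested, ≥ 2 sensitive
(AUC < 0.8), ≥ 2 resistant (AUC > 0.8); Spearman ρ is computed only when
eligible, and positive ρ means high expression accompanies resistance.
Compounds from different response sources are never merged (keys carry a
source prefix). The mRNA–protein check sums the specified isoform
channels and uses Pearson correlation by default (Spearman optional).
CRISPR viability scores are consumed as provided; their normalization is
upstream.

## Synthetic study conditions

The generator is the package's study design, not a tuning knob:

- **Cohort**: eight cancer types × 150 patients, 1200 genes. Latent
  per-sample normals are mapped through the strictly monotone transform
  log10(exp(a + b·z) + 1) with per-gene a ~ N(2, 0.5), b ~ U(0.8, 1.2) —
  log-normal-like FPKM marginals that clear the expression filter and
  preserve all rank statistics exactly.
- **Modules**: target Spearman ρ is planted through the exact normal-copula
  relation r = 2 sin(πρ/6). Defaults: a 60-gene pan-type positive module
  (ρ\* = 0.7), a 40-gene negative module (−0.6), a 40-gene TP53-switched
  module (−0.4 WT / +0.4 MUT), and a 40-gene context-dependent module
  (+0.6 in four types, −0.6 in the other four) that plants two
  cancer-type families for the clustering stage.
- **Mutation status**: Bernoulli(0.5) per sample, split evenly between the
  two functional classes; an optional unknown fraction.
- **Survival**: exponential proportional hazards, baseline 1/1000 per day
  (mean ~2.7 years), log-hazard γ·1[query > type median] with per-type γ
  spanning −1.2 to +0.8, independent uniform censoring with the horizon
  solved (Brent) to hit a 30% expected censoring fraction.
- **Panel**: 25 tumour lines per type plus 3 engineered and 3 fibroblast
  decoys; drug AUC = logistic(location + scale·u) with u copula-linked to
  the query latent (planted ρ +0.6 / −0.6 / 0 for the three default
  compounds); protein = three isoform channels whose sum tracks query
  mRNA at Pearson 0.62.
- **Seeding**: one integer seed; every (cancer type × purpose) stream is
  an independent generator keyed by a CRC of its label, so adding genes
  or types never perturbs unrelated draws. Same seed ⇒ byte-identical
  outputs.

What the generator does **not** emulate: library-size and batch effects,
heavy-tailed count noise, correlated covariates, informative censoring,
gene–gene structure beyond the planted one-factor modules, multi-omic
consistency beyond the single protein channel. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
effect sizes at the stated n — not robustness to the pathologies of real
cohorts.

## Verification problem sizes

The acceptance runs use: 25 random vectors for each exactness oracle;
short lists (n ≤ 10) for enrichment-score enumeration; 200 replicate
null sets × 1000 permutations for p-uniformity (KS at 1%); 50 replicate
500-sample cohorts for planted-set power (q < 0.001, NES > 0); a
300-sample type with a 300-gene ρ\* = 0.7 module over 2300 null genes for
screen recovery; 300 patients per stratum for Δρ recovery; 30 replicates
of n = 2000 for the Cox/rate-ratio comparison, where the geometric-mean
ratio isolates systematic disagreement from the ~2% per-replicate noise
between the two estimators; 5 cohorts of n = 1000 (≥ 300 events) for
log-HR recovery; the enumerated 63-row eligibility truth table; 2 × 10
profile groups at separation 3 vs noise 0.6 for cluster recovery; and a
375-line panel for the protein coupling. Everything completes in about a
minute on one CPU.

## Known limitations

- Gene identifiers are matched exactly and case-sensitively; no alias or
  ortholog resolution.
- No VCF/MAF parsing: mutation input is a pre-tabulated variant-class
  table.
- The stability-based k chooser can accept stable over-splits (above);
  inspect the exported selection table.
- The survival model is overall survival only, no time-varying covariates,
  competing risks, or proportionality diagnostics.
- Full-cohort headline numbers of the motivating datasets require the
  original multi-gigabyte files and are outside the test scope; the
  loaders accept their formats.
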