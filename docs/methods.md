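# Methods

This note records the statistical models implemented in `famscore`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that were genuinely open.

## Mutation statistics

Sub-family mutation frequency multiplies two proportions,
`(m/M) · (n/N)`: the fraction of mutated samples carrying a mutation in
the sub-class and the fraction of sub-class members hit in that cancer.
A sample counts for a sub-class if it has ≥ 1 mutation in any member; `M`
counts samples mutated in *any* gene of the input table, so the statistic
depends on the table's gene universe, not only the family. Sub-classes
overlap in samples, so the frequencies do not sum to anything meaningful
across sub-classes; each lies in [0, 1].

Domain mutation frequency `f(a, j) = d/N` pools instances of one domain
*name* across family genes and counts distinct samples, matching the
per-domain-bar presentation rather than a per-(gene, domain) table.

The domain-enrichment test treats the `N` mutation events of one gene as
i.i.d. uniform over its `L_g` residues under the null, so the in-domain
count is Binomial(N, L_domain/L_g). The p-value is the upper tail
`P(X ≥ k)`, evaluated via the binomial survival function (no subtraction
of near-unity sums, so tiny tails are accurate to full double precision —
verified against exact rational summation to 1e-12 relative error up to
N = 500). The enrichment ratio `E = k/(N·p)` is the observed/expected
density ratio. Decision rule: BH-adjusted p < 0.05 **and** E > 2 **and**
k ≥ 3, strict inequalities; domains with k < 3 are excluded from testing
*and* from the BH family, since including hopeless tests would dilute the
adjustment. Two scopes for the BH family ship: the default pools all
cancers per gene (one test per gene-domain pair per run); `per-cancer`
tests each cancer separately. One-run scoping keeps the adjustment
reproducible regardless of how the input was batched.

A mutation lying in two overlapping domains counts for each; coordinates
are 1-based inclusive (`L = end − start + 1`), the UniProt/Pfam
convention. `N` counts mutation events, not distinct samples — recurrent
hotspot positions contribute each event.

Impact-score comparison uses the two-sided Wilcoxon rank-sum
(Mann–Whitney with tie correction) per score type. SIFT is oriented as
`1 − SIFT` by default so that larger always means more damaging; the raw
comparison is available via `damaging_orient_sift=False`. Whether a
damaging orientation or the raw scale is compared only flips the reported
direction, never the p-value.

## Expression preprocessing and differential expression

Preprocessing is exactly three steps in a fixed order: (1) technical
replicate columns of one (patient, status, cancer) are averaged on the
FPKM scale — averaging precedes the log so that a patient with FPKM 2 and
4 yields log2(3+1) = 2, not the mean of logs; (2) genes with FPKM exactly 0
in **more than** 70% of the remaining samples are removed ("not expressed"
means exactly zero — the natural complement of "non-zero expression in at
least 30% of samples"); (3) values become log2(FPKM + 1). The pseudocount
(1.0) and removal count are recorded in the output metadata. The function
is idempotent: a matrix already flagged log-scale passes through
unchanged.

Differential expression runs an unpaired two-sided Wilcoxon rank-sum per
family gene, tumor vs normal, only in cancers with ≥ 5 normal samples;
BH adjustment is within cancer across family genes, and a gene is called
at FDR < 0.05. The log2 fold-change is the difference of group means on
the log scale — stable for zero-inflated data, and recorded as such.
Unpaired was chosen because a rank-sum (not signed-rank) test is the
stated procedure; pairing information is not required of the input.

Co-expression: all pairwise Spearman coefficients among family genes over
the tumor samples of one cancer, partitioned into within- and
between-sub-class pairs and compared by a rank-sum test. Strong pairs
require SCC > 0.75 with BH-adjusted p < 0.05 by default; a raw-p mode
exists because the two published descriptions of this filter disagree on
adjustment, and the adjusted version is the conservative choice.

## The family score

The ssGSEA enrichment score follows the weighted-ECDF difference formula
with α = 1/4. Implementation details that the formula leaves open:

* **Ties** receive average ranks, preserving Σr = N(N+1)/2; the walk order
  among tied genes is fixed by gene identifier so the score is
  deterministic.
* `|r_j|` is the rank itself (ranks are positive); the absolute value is
  kept in the code for formula fidelity.
* The **raw ES** is the default output. A cohort-level range
  normalization (divide all scores by max − min) ships as an explicit
  opt-in because common ssGSEA implementations differ here and the raw
  formula is the only version actually printed; both modes differ by one
  positive cohort constant, so ranks, groupings and correlations are
  unaffected.
* Set genes absent from the (filtered) matrix are dropped with a logged
  count; an empty intersection or a set covering the whole universe is an
  error (the out-of-set ECDF is undefined).

Dichotomization is by median (ties go to the low group) or by the
survival cutpoint below.

## Immune and pathway association

Genes are ranked by the Spearman correlation of their expression with the
score (vectorized rank-Pearson; ties in SCC broken by gene id). Pre-ranked
GSEA computes the maximum-deviation weighted Kolmogorov–Smirnov running
sum with weights |SCC|^p (p = 1). The null permutes **gene labels**
(random same-size sets) — pre-ranked input has no sample labels to
permute. NES divides the ES by the mean |null ES| of matching sign, the
standard normalization for signed enrichment scores; the p-value is the
matching-sign tail with +1 smoothing, so p ≥ 1/(n_perm + 1) and never
exactly zero. Fewer than 100 permutations is rejected as an unstable
null; sets with < 5 genes in the ranked universe are skipped.

Spearman p-values throughout the package are sample-size adaptive: exact
permutation enumeration for n ≤ 8 (8! = 40320 permutations), a seeded
vectorized Monte-Carlo permutation null (2000 resamples, resolution
5·10⁻⁴) for 9 ≤ n ≤ 30, and the t approximation above. Exact enumeration
for every n up to 30 would be factorially infeasible; 2000 resamples are
ample for 0.05-level screening across the panel sizes involved.

## Clinical endpoints

ROC: AUC is the Mann–Whitney probability estimate U/(n₊·n₋) with ties
contributing ½; the reported curve covers all distinct cutoffs, so
trapezoidal integration reproduces the AUC to machine precision (a tested
identity). Tumor is the positive class.

The survival cutpoint maximizes the absolute standardized two-group
log-rank statistic over midpoints between consecutive distinct scores,
subject to ≥ minprop (default 0.1, the named tool's default) of samples
on each side; ties break toward the lower threshold. The p-value reported
for cutpoint-derived groups is the naive log-rank p of the selected split,
matching the surv_cutpoint/survminer workflow — it is **optimistically
biased** under maximal selection and should be read as descriptive.
Simulations show the selected threshold may sit a few samples inside a
risk group's score support rather than exactly in the gap between groups;
that is inherent to maximal selection, not an implementation artifact.

Cox models use the Breslow tie approximation (statsmodels `PHReg`), the
simplest consistent choice; hazard ratios carry Wald 95% intervals.
Monotone-likelihood separation is detected (non-finite or extreme
coefficients) and returned as a flagged result with infinite-CI sentinels
instead of raising. The classification rule is: risky iff HR > 1 and
p < 0.05, protective iff HR < 1 and p < 0.05, else ns. The Cox covariate
may be the continuous score or the high/low indicator; the group
indicator is the default in the pipeline because the dichotomized
analysis is the one the cutpoint feeds.

Response association collapses RECIST to responders {CR, PR} vs
non-responders {SD, PD} for a two-sided 2×2 Fisher exact test; a `full`
mode keeps the 2×4 table and enumerates its conditional distribution with
fixed margins (log-gamma arithmetic; two-sided by summing tables no more
probable than the observed one, the standard ordering).

## Synthetic data

The generators emulate the *statistical structure* of the real cohorts,
nothing more:

* **Mutations**: Poisson counts per (sample, gene) — the simplest count
  model — with mean `per_gene_rate` (default 0.02, a realistic
  per-gene/per-sample load for mid-size proteins); positions uniform over
  the protein except planted hotspots, where the in-domain density is
  multiplied by θ and renormalized, giving
  P(in) = θf/(θf + 1 − f) for coverage f. Impact scores derive from a
  latent damaging value shifted upward in-domain by `impact_shift`
  (default 1 SD), mapped to SIFT/PolyPhen-like (0, 1) scales and a
  CADD-like scale.
* **Expression**: log2-scale multivariate normal; per-gene baselines
  N(3, 1), family genes within one sub-class share an equicorrelation ρ
  (default 0.5; Spearman image (6/π)·asin(ρ/2)), tumor samples add
  `tumor_shift` log2 units (default 1.5) to family genes, export via
  2^x − 1 truncated at 0.
* **Clinical**: exponential event times with hazard λ₀·exp(β·z) in the
  standardized score z (defaults λ₀ = 1/365 per day, β = log 2 per SD);
  independent uniform censoring with the scale tuned by bisection so the
  realized censored fraction matches the request (default 0.3). Response
  is Bernoulli through a logistic link in z; responders split CR:PR = 1:2
  and non-responders SD:PD = 1:1 — an arbitrary but fixed rule recorded
  in the truth record.
* **Immune features**: Gaussian copula — the score's normal scores,
  feature latents at Pearson 2·sin(π·SCC/6) (the exact Spearman
  correspondence for bivariate normals), log-normal marginals; the
  configured cell-fraction block is renormalized to sum to 1 per sample.
  Renormalization perturbs the realized rank correlations slightly (the
  compositional constraint couples features); with the default block of
  six cell types the targets are met within a few hundredths at n = 400.

Each generator derives its random stream from (stage id, seed), so stages
are individually reproducible and the whole pipeline is deterministic
under one seed. Each returns a truth record naming everything planted.

What passing tests on these cohorts demonstrate: correct formulas,
calibrated error rates, and recoverable planted effects *under the stated
generative models*. What they do not demonstrate: behavior under real
TCGA/GEO mutational signatures, expression distributions, batch effects or
dependence structures — none of which the generators attempt to mimic.
The analyses of the original cohorts require controlled-access downloads
and are verification targets outside the scope of the shipped test
surface; the accessions are listed with the fixtures' provenance notes.

## Problem sizes in the shipped checks

The acceptance surface uses cohorts sized for a single CPU: hotspot
recovery over 200 seeds of ~40-event genes, differential expression over
100 seeds of 30 + 30 samples, Cox recovery over 100 cohorts of n = 400
(~30% censored), log-rank calibration over 1000 null replicates of
n = 100, and a demo pipeline of 3 pseudo-cancers × 120 samples × ~580
genes — sizes at which every targeted property (power ≥ 90–95%, nominal
error control, machine-precision identities) is comfortably measurable.

## Known limitations

* Single-covariate Cox only; no multivariable adjustment, competing
  risks, or time-dependent covariates.
* The 77-gene family table and the 78-regulator panel are reconstructions
  with approximate coordinates, intended as editable defaults, not as an
  authoritative annotation.
* The cutpoint log-rank p is selection-biased (see above); no
  maximally-selected-statistic correction is applied.
* Pre-ranked GSEA reports no leading-edge genes, and over-representation
  analysis of DEG lists is out of scope (its term universe would pin an
  external annotation snapshot).
* No normalization beyond the stated preprocessing (no TMM/quantile/RMA/
  batch correction); impact scores and infiltration fractions are inputs,
  never computed.
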