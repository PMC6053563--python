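# Methods

This note documents the statistical machinery in `ssrpopgen`: the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Data model and conventions

Genotypes are diploid, codominant, multi-locus, grouped into sampling
areas. Allele codes are the integers as genotyped (typically fragment or
repeat sizes) and are never binned; the stepwise mutation models in the
bottleneck machinery rely on this ordering. Allele code 0 marks a missing
gene, and a half-missing call is normalised to fully missing (the GenePop
convention; it keeps per-locus gene counts even). Pooled (species-level)
allele frequencies weight areas by gene count, i.e. they equal a direct
recount of the pooled sample.

Coordinates are parsed from D°M′S″ strings to signed decimal degrees and
treated as spherical (haversine, R = 6371.0088 km). At the 10–250 km scale
of the Mantel analyses the sub-kilometre ellipsoidal error is irrelevant.

## Diversity statistics

Per locus, observed heterozygosity `Ho` is the heterozygote fraction among
typed genotypes and `He` is Nei's unbiased gene diversity
`(2n/(2n−1))(1 − Σp²)`. Per-area values are unweighted means over loci
with data (the FSTAT convention, matching single-value-per-area summary
tables). The effective number of alleles is `Ae = Σ_l 1/(1 − He_l)`
(summed over loci), reported also as a whole-number percentage of the
observed allele count k. Allelic richness uses El Mousadik–Petit
rarefaction, `A_ri,l = Σ_a [1 − C(2n−N_a, g)/C(2n, g)]`, with g defaulting
per locus to twice the smallest typed sample across areas; binomial
coefficients are evaluated through log-gamma for stability. A private
allele occurs in exactly one area; a rare allele has pooled frequency below
0.05 (configurable) and is not private — the threshold is the conventional
5% cutoff, which reproduces the qualitative rare ≫ private pattern of
typical SSR surveys.

The within-area fixation index is the single-population Weir–Cockerham
estimator: per allele, `b = n/(n−1)[p(1−p) − (2n−1)/(4n)·h]` and `c = h/2`,
with the multilocus `f = 1 − Σc/Σ(b+c)` a ratio of summed components.
Significance permutes alleles among individuals within area and locus
(two-sided on |f|); CIs are percentile bootstraps over loci. Desk-scale
default is 1,000 permutations; the original surveys' 110,000/121,000 are a
config knob. The apparent outcrossing rate `t_a = (1−f)/(1+f)` is reported
raw (values above 1 arise from negative f and are clipped only in rendered
tables).

## Exact tests and null alleles

**HWE.** The Markov-chain exact test runs a random-transposition walk on
the arrangement of the 2n genes into n genotypes; the uniform stationary
distribution over arrangements induces exactly Levene's conditional
distribution over genotype tables, so no Metropolis correction is needed.
The p-value is probability-ordered (Fisher convention): the chain fraction
of tables no more probable than the observed one, with a standard error
from batch means. Defaults are 10,000 dememorization steps, 100 batches of
10,000 iterations.

**LD.** The genotypic (phase-free) test of independence on the two-locus
genotype contingency table: a Metropolis chain over tables with fixed
margins under the multiple-hypergeometric null, ordered by the
log-likelihood-ratio statistic. No haplotype phasing is attempted.

**Null alleles.** The EM treats each apparent homozygote `i/i` as a
mixture of a true homozygote (weight `p_i/(p_i + 2r)`) and a visible/null
heterozygote, and blank genotypes as candidate null/null homozygotes.
Iteration stops when the largest frequency change falls below 1e-8; the
observed-data log-likelihood is asserted non-decreasing. The conventional
`r > 0.20` alarm flag is attached. Estimates feed the ENA-corrected
pairwise FST: per (area, locus) the visible-allele frequencies are
re-estimated by the EM, the null state is excluded and the visible
frequencies rescaled before variance components are computed; with `r = 0`
this is the identity. Bit-parity with any particular legacy binary is not
claimed — the algorithmic contract is what is implemented and tested.

Bonferroni thresholds are computed exactly (`α/n_tests`) and rendered at
4–5 significant decimals in reports.

## F-statistics and gene flow

Weir & Cockerham (1984) variance components are computed per allele and
locus with the n_c correction for unequal sample sizes; multilocus
estimators are ratios of summed components, so the identity
`(1−F_IT) = (1−F_IS)(1−F_ST)` holds to machine precision by construction.
CIs come from percentile bootstrap over loci (10,000 replicates by
default); the significance of θ from permuting individuals among areas.
Negative θ estimates are reported as computed, never truncated.

Island-model gene flow uses the Crow–Aoki finite-island correction
`Nm = (1/(4α))(1/θ − 1)` with `α = (n/(n−1))²` and n the number of sampled
areas. This reading of α (a typeset formula in the source literature is
ambiguous) is adopted because it reproduces the published migrant numbers
from the published θ values at printed precision; n = 11 areas, not the
individual count, enters α for the same reason.

## Coancestry and effective size

Loiselle pairwise kinship sums, over loci and alleles,
`(x_i−p)(x_j−p) + p(1−p)/(2n−1)` in the numerator against `Σ p(1−p)`, with
dosages x ∈ {0, ½, 1}; the multilocus coefficient is the ratio of sums and
pairs missing a locus skip it in both sums. The estimator is *relative* to
its reference allele frequencies: referenced to the area's own sample, the
mean pairwise kinship is ~0 by construction, so the per-area Ne driver
defaults to the pooled sample as reference (the SPAGeDi convention), under
which within-area family structure registers as positive mean kinship. The
raw kinship operation keeps the self-referenced default.

Group coancestry is `Θ̄ = [n·s + n(n−1)·f̄]/n²` with self-coancestry
`s = (1+F)/2` and f̄ the mean off-diagonal kinship; negative F (for the
self term) and negative f̄ are floored at zero — an individual's coancestry
with itself cannot fall below ½, and negative mean relatedness would
inflate Ne past the sample size. Effective size is

    Ne = 0.5 / [ Θ̄ (n−1)/n + (1+F)/(2n) ]

(the typographically garbled published equation resolved to the
Cockerham-derived form with the correct limits). Two consequences worth
stating plainly: an unrelated, non-inbred sample has `Θ̄ = 1/(2n)` and
hence `Ne = n²/(2n−1) ≈ n/2`, so Ne/N ≈ 0.5 is the *ceiling* behaviour for
a random sample under this formula — consistent with the 0.31–0.59 range
of published surveys using it — and Ne decreases monotonically in both Θ̄
and F.

## Bottleneck tests

A recent bottleneck removes rare alleles faster than gene diversity, so
observed He exceeds the equilibrium expectation Heq given the observed
allele number k. Heq is simulated by a neutral coalescent for the 2n
sampled genes: exponential coalescence times, mutations Poisson on total
branch length, placed uniformly; allele states propagate from the root
under IAM (each mutation a novel allele — only the most recent on a
lineage matters), SMM (±1 steps) or TPM (single step with probability
0.95, else a symmetric geometric jump with magnitude variance 12 — the
"12 variations, 95% SMM" convention). The mutation parameter θ is tuned by
bisection so the expected allele number matches k (closed form under IAM,
pilot simulation otherwise), then replicates are rejection-sampled to
exactly k; acceptance below 0.1% aborts with guidance. Per locus the
report gives `DH = He_obs − E[Heq]`, standardized by sd[Heq].

Note the model ordering: at matched k, mean Heq is *higher* under SMM than
IAM (homoplasy evens out allele frequencies), which is why SMM is the
conservative null for excess detection.

The sign test compares the observed number of excess loci with its
Poisson-binomial distribution under per-locus excess probabilities
estimated from each locus's own null sample; the p-value doubles the
smaller inclusive tail, capped at 1. Because the count statistic is
discrete over ~10 loci, this p-value is *valid* (P(p ≤ α) ≤ α, verified by
exact enumeration in the tests) but not uniform — the cap puts an atom at
p = 1 whenever the observed count is the null median, so roughly a fifth of
equilibrium datasets score exactly 1. The Wilcoxon signed-rank test on the
DH values (exact by dynamic programming up to 25 loci, zeros dropped, ties
mid-ranked, normal approximation with continuity correction above) is
calibrated essentially uniformly and is the better-behaved of the two.

Loci are never dropped automatically; an explicit exclude list reproduces
filtering decisions auditable in the report.

## Among-area structure

AMOVA encodes individuals as allele-dosage vectors, uses squared-Euclidean
distances (pairs missing a locus average over shared loci, rescaled), and
partitions sums of squares among/within areas; Φ_ST is the among-area
variance fraction and its p-value permutes individuals among areas
(default 1,000 at desk scale; 20,000 matches the original analyses). Nei
distance defaults to the 1978 unbiased variant (1972 available); UPGMA
joins the lexicographically smallest pair among ties, and node support is
the percentage of locus-bootstrap trees containing the same leaf set.
The Mantel test is one-tailed for positive association (the
isolation-by-distance hypothesis), with full enumeration of permutations
for up to six areas and 9,999 random permutations otherwise, on
great-circle kilometres.

## Admixture clustering and DAPC

The Gibbs sampler alternates allele-copy origins Z | P,Q, cluster
frequencies P | Z (Dirichlet(λ=1) prior, or the correlated F-model prior
`Dirichlet(p̄(1−F)/F)` around pooled frequencies behind a flag), admixture
proportions Q | Z (symmetric Dirichlet(α)), and a Metropolis step on α
(uniform prior on (0, 10], clamped to [1e-3, 10]). The independent-
frequency model is the default: at the divergence levels of interest it
recovers ΔK equally well and mixes faster. Model evidence is estimated as
`mean(L) − var(L)/2` over post-burn-in log-likelihoods; this estimator
carries a known positive bias of order 1 log-unit relative to the exact
marginal likelihood (the tests pin the sampler to the estimator's own
analytic limit on a closed-form fixture rather than to the marginal).
Cluster labels are canonicalized by total membership. Desk-scale defaults
are 2,000 sweeps / 500 burn-in; the 500,000/200,000 convention of
full-scale runs is configurable. ΔK follows Evanno:
`|L(K+1) − 2L(K) + L(K−1)|/sd(L(K))` over replicate runs, undefined at the
K extremes and at zero sd.

DAPC centres and scales the dosage matrix (missing dosages mean-imputed),
projects onto a chosen number of principal components and runs linear
discriminant analysis on the group labels; axis counts are user-set, with
no automatic a-score optimisation.

## Synthetic data: what it does and does not emulate

The main generator draws ancestral allele frequencies Dirichlet(1) over
8–14 states per locus, area frequencies from the Balding–Nichols
distribution `Dirichlet(p̄(1−F)/F)` (exact expected FST, instant to
sample), and genotypes by an identity-by-descent mixture: with probability
F_IS both genes copy one draw. Defaults mirror the motivating survey
design — 11 areas, 16–30 diploids per area, 10 loci, within-area
inbreeding 0–0.28, among-area F around 0.04–0.06. Null alleles are
overlaid gene-wise (null/visible → visible homozygote, null/null →
missing, the classic unobservable apparent-null-homozygote), then missing
data. Bottleneck histories come from a forward Wright–Fisher simulation
with SMM mutation; desk-scale runs keep θ = 4Nμ ≈ 2 (typical of SSR loci)
by simulating N_eq = 100 with a proportionally rescaled mutation rate, and
flagged areas spend the final G generations at the reduced size N_b.

What passing tests on these data show: the estimators recover the
parameters of an island-model-like, mutation-drift world with independent
loci. What they do not show: robustness to genotyping error other than
null alleles (stutter, large-allele dropout), linked loci, selection,
spatially continuous structure within areas, or uncertainty in the
published tables themselves.

## Problem sizes used in the checks

The verification experiments run at sizes chosen to make their statistical
assertions sharp while staying desk-scale: estimator recovery averages 100
Balding–Nichols replicates of the full 11 × 30 × 10 design; exact-test
calibration uses 200 replicates (KS at α = 0.01); null-allele recovery
uses n = 500 diploids; the bottleneck direction check uses 50 paired
forward simulations (N_b = 10 for 20 generations against matched
equilibrium runs); ΔK recovery uses 20 batches of replicate Gibbs runs on
four areas in two tiers. Enumeration oracles (tiny HWE tables, rarefaction
subsampling, three-taxon UPGMA, three-label Mantel, six-locus
Poisson-binomial) are exact.

## Known limitations

- The admixture evidence estimator's bias means ln-prob values are
  comparable across K (which is all ΔK needs), not absolute marginal
  likelihoods.
- The Heq conditioning-on-k scheme (bisected θ + rejection) matches the
  standard contract but not any specific legacy binary bit-for-bit.
- The sign test's doubled-tail p-value is conservative, not uniform (see
  above); treat its borderline values accordingly and prefer the Wilcoxon
  p for calibrated inference.
- ENA correction re-uses observed heterozygote frequencies alongside
  EM-corrected allele frequencies in the variance components; this is the
  documented contract ("exclude null, rescale visible, recompute"), exact
  in the r = 0 limit.
- Per-area Ne values of the motivating survey cannot be reproduced without
  its raw genotypes; only aggregate identities over the published tables
  are checked.
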