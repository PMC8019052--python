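# Methods

This note documents the models, defaults, and numerical choices behind
charpop, and what the synthetic-data experiments do and do not demonstrate.

## The synthetic study

The generator (`charpop.simdata`) emulates a two-watershed study design:
263 fish across seven lakes in two groups (closed "Fog": Fog1/2/3/5 with
n = 19/9/79/18; leaky "LTER": LTER345/347/348 with n = 29/24/85), 15,000
biallelic SNPs on 12 chromosomes at full scale (tests and the acceptance
script use 300–5,000 loci; replicate counts and sample sizes are stated with
each experiment below).

**Genotypes** follow a two-level Balding–Nichols model: ancestral allele
frequencies p ~ Beta(0.8, 0.8) (clipped to [0.01, 0.99]); group frequencies
~ Beta(p(1−F_b)/F_b, (1−p)(1−F_b)/F_b) with F_b = 0.2; lake frequencies
drift a further F_w = 0.02 around their group (the study reports strong
between-group divergence and weak, nonzero within-group structure; F_w is an
exposed knob because no within-group value is fixed by the design).
Genotypes are Binomial(2, p_lake); missing calls are planted uniformly at
rate 0.15.  F = 0 is handled as the degenerate limit (frequencies copied).
The nesting has a measurable consequence: Hudson-type F_ST between *pooled*
groups lands slightly below the nominal F_b (≈0.175 at the full nested
defaults) because pooled-group heterozygosities absorb the within-group
divergence; the flat two-deme design used in the recovery experiments
estimates 0.2 without that bias.

**Sex-linked region.**  Males are heterogametic.  Three chromosomes are
reserved: four diagnostic XY loci (heterozygous in every male,
homozygous-reference in every female; optional error rate ≤ 1%, default 0)
split across two chromosomes, and one locus genotyped only in females on a
third.  The same two XY chromosomes also carry a partially degenerate
sex-linked background (default 2% of loci): males carry one fixed
Y-haplotype allele plus an X copy drawn at frequency p_x ~ U(0.05, 0.3),
females two X copies.  This background is what makes a *sex axis* exist at
all: five clean loci among thousands contribute an eigenvalue of order
n·5·0.25/L to the genotype covariance, far inside the random-matrix bulk at
any realistic n/L, whereas real salmonid sex chromosomes carry a
differentiated region spanning many markers.  Background loci never satisfy
the diagnostic detection patterns, so detection sensitivity/false-positive
counts are still scored against exactly the five planted pattern loci.
Females take the extra fish when n is odd so the female-only locus stays at
≤ 50% site missingness and survives the default filter.

**Phenotypes.**  Total length is drawn from a per-lake Gaussian mixture
(Fog3: 0.57·N(160, 15²) + 0.43·N(350, 40²); LTER348: 0.75·N(388, 45²) +
0.25·N(565, 20²); other lakes unimodal with means 254–485 mm); negative
draws are rejected.  The nine linear traits follow M = a·L^b·exp(ε),
ε ~ N(0, σ²) with σ = 0.05 and per-trait intercepts/exponents around
isometry (b 0.90–1.10, a chosen so traits are realistic fractions of body
length).  Crucially there is a *single* allometry for all fish: any
clustering structure in raw traits is size, not shape — the generator's
ground truth is "plasticity only", and the mixture component index is the
true size class.

**Otoliths.**  Each fish gets an age (uniform on 5–10 years), a saturating
length-at-age curve L_a = L0 + s(1 − e^{−ka}) ending at its capture length
(k ~ U(0.15, 0.35)), and radii O_a = O0 + c(L_a − L0) with per-fish
proportionality c ~ N(0.004, 0.0003²) and true hatch radius O0 = 0.05.
Annual increments of this curve decline exponentially with age, so the
log-increment–age regression used for the biological intercept is correctly
specified.  Lognormal noise (sd 0.05) perturbs radius increments,
preserving monotonicity.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), genotyping error and allele-specific missingness, genotype
likelihood uncertainty (all statistics are computed from called genotypes —
the original analyses used genotype likelihoods for diversity statistics,
so no numeric diversity anchors are claimed), selection, age–length
coupling in sampling, and measurement error in traits.  Passing tests
demonstrate method correctness and recovery under this model, not
performance on real GBS data.

## Morphometrics

Allometric slopes are per-trait OLS on log10 scale; the reference length is
the arithmetic mean of the fitting set (all fish for across-lake analyses,
within-lake fish for within-lake analyses).  Clustering fits Gaussian
mixtures for K = 1..5 over four covariance families (spherical, diagonal,
shared full, per-cluster full — scikit-learn's parameterizations; the
shared-spherical and shared-diagonal variants add nothing to the selection
behaviour), 10 k-means++ initializations per fit, variance floor 1e−6.
BIC uses the higher-is-better convention 2·logL − m·log n.  If the best
model's gap to the best model at a *different* K is below 3, the selection
is flagged ambiguous and the smaller K is reported (conservative morph
claims).  Rows with missing traits are dropped and counted.  Clusters are
named small/medium/large by increasing mean total length; ties break by
cluster index with a warning.

## Growth

The biological intercept fixes hatch length at 17 mm; the hatch radius is
estimated per fish among the five youngest (minimum age 3) by regressing
log10 annual increment on age over ages ≥ 2 — the first-year increment is
unobservable without O0 — extrapolating to age 1 and subtracting from the
first annulus radius, then averaging fish-level estimates.  Fish-level
(rather than pooled) regressions keep the estimate exact when growth rates
vary between fish; with zero noise the round trip to planted lengths-at-age
is exact to machine precision, and recovery is within ±5% at increment
noise sd 0.01.  Negative extrapolated radii floor at 0.  Ages are integer
annuli; no partial-year interpolation.

## Genotype matrix, filtering, PCA

Genotypes count the per-locus minor allele (recomputed over nonmissing
calls at load; ties keep ALT).  Filters run in a fixed order — site
missingness ≤ 50% (30% for the stringent variant), MAF strictly > 0.01 over
nonmissing calls, positional thinning keeping the first site of each run
with a 90 bp minimum gap (the cited tool's semantics), then individuals
with > 80% missing cells dropped — with per-step removal counts reported.
Distance thinning is used; thinning by assay-locus id would be a variant if
locus boundaries were known.

The covariance between two individuals is the mean product of per-locus
centred genotypes over the loci both were called at.  This
pairwise-complete estimator need not be positive semidefinite; the
eigendecomposition proceeds and negative eigenvalues are reported, not
clipped (their scores use the clipped sqrt).  Scores are eigenvectors
scaled by √λ, ordered by λ, sign-fixed so the largest-magnitude coordinate
is positive.  Pairs sharing zero loci get covariance 0 with a warning.

## Divergence and diversity

Reich–Patterson F_ST uses the ratio-of-sums (weighted) form; loci with
fewer than two called copies in either population are excluded and counted.
CIs are percentile 2.5/97.5 over 100 locus bootstraps; degenerate
replicates (ΣD = 0) are redrawn and counted.  Watterson's θ divides the
a(n)-weighted segregating-site count by the number of assayed sites with
n ≥ 2 called copies, using each site's own allele total.  He is reported
both raw (2p̂q̂) and with the n/(n−1) small-sample factor; F_IS = 1 −
mean(Ho)/mean(He) uses the raw He so the all-heterozygote case is exactly
−1.  The relationship matrix is W·Wᵀ/(2Σp(1−p)) with missing entries
mean-imputed (count reported) and monomorphic loci excluded; modality of
the off-diagonal values is judged by a 1- vs 2-component mixture with the
same ΔBIC ≥ 3 rule (panmixia ⇒ unimodal).

## Sex-linked locus detection

The sex axis is found by scanning the first 10 PC axes (axis order is
dataset-dependent); an axis qualifies only if its two-component 1-D mixture
beats one component by ΔBIC ≥ 3, the split perfectly separates the
known-sex fish, and — when lake labels are available — both clusters occur
within every lake of 20+ fish (minority fraction ≥ 0.1).  Both gates
matter with only six known fish: a unimodal noise axis separates them by
chance ~3% of the time per axis, and a *population-structure* axis (which
is genuinely bimodal) matches them whenever the known fish happen to split
3|3 along lake groups, another ~3% coincidence; sexes, unlike lakes, are
interleaved ~1:1 within every lake.
DAPC retains the number of leading PCs minimizing root-mean-squared
assignment error over 30 stratified 90/10 holdouts, and SNP loadings are
the projections of centred genotype columns on the discriminant axis.
Candidates are loci above the 0.999 loading quantile (minimum 3 inspected)
plus any locus with call rate < 5% in one sex and > 50% in the other — a
one-sex locus has *no* genotype-value signal along the axis because its
missing entries are centred to zero, so loadings cannot rank it.
Classification thresholds are strict inequalities (heterozygosity exactly
0.95 does not qualify).  Whole chromosomes carrying any classified SNP are
removed.  F_ST between putative sexes is reported as context only.

## Ancestry, stocks and exact tests

The admixture model is maximized by block EM (10 random starts, tolerance
1e−3 on the log-likelihood, probabilities clipped to [1e−9, 1−1e−9];
missing genotypes skipped; K = 1 closed form).  K is selected by 10-fold
cross-validation masking nonmissing genotype *cells* and scoring the mean
squared error of predicted dosage (2 starts, 150 iterations per fold fit —
CV needs relative, not converged, fits); ties go to the smaller K.  One
property worth knowing: on panmictic data the ML fit overfits Q somewhat
(mean max-Q ≈ 0.75, not uniform rows) — a Bayesian prior would shrink it —
while diverged demes give essentially hard rows (> 0.95); the CV criterion,
not Q itself, is what identifies K = 1.  The stock model assigns whole
individuals to K stocks; bootstrap support is the fraction of 100
locus-resampled refits (warm-started, label-matched by maximal overlap)
agreeing with the full-data assignment.  Fisher's exact test is exact
(hypergeometric tail) for 2×2 and Monte-Carlo (10⁵ label permutations,
seeded) for larger tables.  The k-means group finder uses the BIC
n·log(WSS/n) + K·log(n) (lower is better), which behaves as intended in
higher-dimensional score spaces (many retained PCs); in very low dimension
it over-splits, as its R analogue does.  Assignment accuracy matches
clusters to labels by the Hungarian algorithm, so it is label-switching
invariant.

## PERMANOVA

McArdle–Anderson trace formulation on Euclidean distances (optional
column standardization): total SS = tr(G) with G the Gower-centred squared
distance matrix; each term's SS is tr(H_full·G) − tr(H_reduced·G) (marginal,
Type-II); pseudo-F = (SS_t/df_t)/(SS_r/df_r); p = (#{F_perm ≥ F_obs} + 1)/
(n_perm + 1) by free row permutation (a strata option restricts shuffles).
Collinear terms (zero marginal df) are dropped with a warning.  The primary
response for the ecological analysis is the per-lake size-class composition
(7 lakes); a per-fish trait response with replicated lake covariates is
possible but pseudo-replicates lake effects.  The additive model search
evaluates all subsets up to 3 terms and ranks by (all terms significant at
0.05, then smallest residual SS).  Correctness anchors: the univariate
pseudo-F equals the classical ANOVA F algebraically, and the test suite
cross-checks marginal SS and F against R vegan's adonis2(by = "margin").

## Evaluation experiment sizes

As run by `scripts/acceptance.py` and the acceptance tests: F_ST recovery —
100 replicates of two demes at F = 0.2, 50 fish each, 5,000 loci, 100
bootstraps; PERMANOVA calibration — 500 null datasets (n = 21, 3 response
columns), 999 permutations; morphometric contrast — 20 replicates of a
400-fish bimodal lake; sex-linkage — 20 replicates of the full 7-lake
design at 5,000 loci; structure negative control — 50 replicates of a
60-fish panmictic bimodal lake at 300 loci, K ∈ 1..3; positive control —
two 30-fish ecotypes at F = 0.2, 500 loci.  These sizes give stable
verdicts for every statistic while the whole evaluation completes in a few
minutes on one core.

## Known limitations

Statistics are computed from called genotypes, not genotype likelihoods —
on low-coverage real data the diversity statistics especially will differ
from likelihood-aware estimates.  Independent loci mean LD pruning is
untested beyond its positional mechanics.  The EM ancestry model replaces
MCMC-based hierarchical inference; cross-validated K and DIC-selected K
agree on the synthetic designs here but are not guaranteed to agree in
general.  The PERMANOVA with 7 lakes has 3–4 residual df: power is low and
only large effects can be detected, as in any seven-lake design.
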