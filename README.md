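# charpop

Morphological and population-genomic divergence analysis of lake-resident
arctic char (*Salvelinus alpinus*).

Arctic char frequently form coexisting morphs — dwarf and normal ecotypes in
the same lake — and a recurring question is whether observed size structure
reflects genetically distinct ecotypes or plastic growth variation.  This
package re-implements, as a tested pipeline over synthetic data with known
ground truth, the analysis chain used to answer that question for char
populations in two groups of small arctic Alaskan lakes ("closed" Fog lakes
vs "leaky" LTER lakes): allometric trait correction and model-based
size-class detection, GBS SNP filtering and genotype-covariance PCA,
divergence and diversity statistics, sex-linked locus detection and removal,
model-based ancestry inference, otolith back-calculation of growth, and
PERMANOVA of size structure against lake-level ecology.

It is aimed at fish ecologists and population geneticists who want the
individual steps (each exposed as a library function) or the end-to-end
workflow with a generator that emulates the study design.

## The core methods

**Allometric size adjustment.** A trait *M* measured on a fish of total
length *L* is rescaled to the mean length *L<sub>m</sub>*:

    log10 Y = log10 M + b (log10 Lm − log10 L)

with *b* the OLS slope of log10 M on log10 L.  Size classes are then sought
by Gaussian-mixture clustering over K and covariance family, selecting the
model that maximizes BIC = 2 logL − m log n with a ΔBIC > 3 rule.

**Reich–Patterson F_ST.**  With allele count *a* of *n* sampled copies per
population and *h = a(n−a)/(n(n−1))*,

    N = (a1/n1 − a2/n2)² − h1/n1 − h2/n2,   D = N + h1 + h2,
    F_ST = ΣN / ΣD   (ratio of sums over loci),

unbiased for small and unequal samples; 95% CIs come from 100 bootstrap
replicates over loci.

**Sex-linked loci.**  Males are the heterogametic sex: a PCA axis that
splits individuals into two clusters matching fish of known sex defines
putative sexes; DAPC between them ranks SNP loadings, and candidates are
classified XY-like (heterozygosity > 0.95 in one sex, < 0.05 with one
dominant homozygote in the other) or one-sex-genotyped (call rate < 5% in
one sex, > 50% in the other).  Implicated chromosomes are removed.

**Ancestry and stocks.**  The admixture likelihood
Π Binom(x; 2, Σ<sub>k</sub> q<sub>ik</sub> p<sub>lk</sub>) is maximized by
block EM; K is chosen by 10-fold cross-validation masking genotype cells.  A
whole-individual stock mixture (K = 2, locus bootstrap for assignment
support) is compared against morphological size classes with Fisher's exact
test.

**Growth.**  Biological-intercept back-calculation,
L<sub>a</sub> = L<sub>c</sub> + (O<sub>a</sub> − O<sub>c</sub>)(L<sub>c</sub> − L<sub>0</sub>)/(O<sub>c</sub> − O<sub>0</sub>),
anchored at a 17 mm hatch length, with the hatch radius O₀ estimated from
the log-increment–age regression of the five youngest fish.

**PERMANOVA.**  McArdle–Anderson trace form on Euclidean distances with
marginal (Type-II) sums of squares and free row permutation; for a
univariate response the pseudo-F equals the classical ANOVA F exactly.

## Worked example

```python
from charpop import simdata, morphometrics as mm

study = simdata.simulate_study(simdata.default_config(seed=1, n_loci=5000))
fish = study.fish
traits = fish[[f"{t}_mm" for t in mm.TRAIT_NAMES]]
lengths = fish["total_length_mm"].to_numpy()

model = mm.fit_allometric_slope(traits, lengths)
adjusted = mm.size_adjust_frame(traits, lengths, model)
raw = mm.gmm_cluster(traits.to_numpy(), k_max=5, seed=0)
adj = mm.gmm_cluster(adjusted.to_numpy(), k_max=5, seed=0)
print(raw.k, adj.k)
```

prints `2 1`: clustering the raw traits finds the planted size classes
(ΔBIC ≈ 97 over the runner-up), while the size-adjusted traits collapse to
a single morph (ΔBIC ≈ 61 in favour of K = 1) — the size structure is
allometric plasticity, not distinct morphology.  The numbered scripts under
`analysis/` run the full chain on the same synthetic study; for example
`analysis/05_sexlink.py` reports the sex axis (PC2), 100% putative-sex
agreement with truth, exactly five classified sex-linked SNPs on three
chromosomes, and F_ST ≈ 0.014 between putative sexes, and
`analysis/06_popstats.py` prints a between-group F_ST near the planted 0.2
with within-group lake pairs an order of magnitude lower.

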