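# Methods

`clinemap` implements Bayesian genomic-cline analysis for admixed
("hybrid-zone") populations: per-locus estimation of cline steepness and
centre relative to the genome-wide hybrid index, WAIC-based detection of
loci whose ancestry clines are too steep to be explained by genome-wide
admixture (restricted introgression), pooling of such loci into candidate
regions, and the downstream association statistics. A synthetic generator
with known truth stands in for real resequencing data throughout
development and testing.

## Model

**Hybrid index.** For diploid individual *i*, the hybrid index
*h<sub>i</sub>* ∈ [0, 1] is the proportion of the genome inherited from
source population S1 (0 = pure S0, 1 = pure S1). Given per-locus source
allele frequencies *p*₀ₗ, *p*₁ₗ (the frequency of the focal allele in S0
and S1), each non-missing allele copy of individual *i* at locus *l* is the
focal allele with probability

    f_il = h_i · p1_l + (1 − h_i) · p0_l.

The per-sample posterior (Beta(1, 1) prior by default) is sampled by
adaptive random-walk Metropolis on logit(*h*), all samples advanced as
independent vectorised chains. Default chain length 2000 with burn-in 1000;
step sizes adapt toward 0.44 acceptance by Robbins–Monro during burn-in
only, so the post-burn-in kernel is fixed. With p₀, p₁ fixed at their
posterior means the *point* estimates are accurate but the 95 % intervals
mildly undercover, since source-frequency uncertainty is ignored;
redrawing the frequencies from their Beta
posteriors each iteration (`resample_freqs=True`, with a few thousand
post-burn-in draws for stable quantiles) restores near-nominal coverage
and is what the interval-calibration test exercises.

**Genomic cline.** The logit-logistic cline maps the hybrid index to the
probability that an allele copy at locus *l* carries S1 ancestry:

    phi(h; v, c) = logistic( v · (logit h − logit c) ),

with steepness *v* > 0 (*v* = 1: the locus mirrors genome-wide admixture;
*v* > 1: restricted gene flow across the centre) and centre *c* ∈ (0, 1)
(the hybrid index at which the locus frequency is halfway between the
source frequencies; *c* ≠ 0.5 is directionally biased introgression; the
derived latent shift *u* = *v*·logit *c* is also reported). The
observation model is

    P(focal copy) = phi(h_i; v_l, c_l) · p1_l + (1 − phi) · p0_l,

with *h<sub>i</sub>* fixed at its posterior mean and source individuals
entering at *h* = 0 / *h* = 1 exactly (their terms are then constant in
(*v*, *c*)). Parameters are sampled on the latent scale (ln *v*, logit *c*)
— where the posterior is near bivariate normal — under independent
Normal(0, 10) priors, by a joint adaptive random-walk (target acceptance
0.25; default 5000 iterations, burn-in 2000, all loci as vectorised
chains). Original-scale summaries are posterior means of the transformed
draws (not transforms of latent means); intervals are equal-tailed
quantiles. Bayesian two-sided p-values for ln *v* = 0 and logit *c* = 0 use
normal tail approximations from the latent mean and SD. Loci monomorphic
among usable observations are flagged `degenerate`, not forced.

**Model comparison.** Each locus is re-fitted with *v* pinned to 1 (only
logit *c* sampled) and both fits are scored by the widely applicable
information criterion,

    waic = −2 (lppd − p_waic),

computed pointwise over **allele copies** (the unit of the likelihood
factorisation): lppd is the summed log posterior-mean pointwise likelihood
(log-sum-exp stabilised) and p_waic the summed posterior variance of the
pointwise log-likelihood (sample variance, S−1). Δwaic = waic(full) −
waic(reduced); negative values support locus-specific steepness. Because a
rejected proposal repeats the previous state, the per-locus WAIC pass
evaluates the pointwise likelihood once per unique chain state and weights
by run length — an exact reformulation that cuts the dominant cost ~4×.

**SCVs and regions.** A variant is a steep-cline variant (SCV) when
ln *v* > 2.3 (i.e. *v* > 10) **and** Δwaic < −10, both strict — a
deliberately conservative joint rule. SCVs are classed by posterior-mean
centre: *c* ≤ 0.45 (S1-biased), *c* ≥ 0.55 (S0-biased), otherwise unbiased
(boundaries inclusive). Candidate regions pool consecutive SCVs on a
chromosome whose gaps are strictly below 50 kb; regions with fewer than 10
members are dropped; region bounds are the first/last member positions
(no flanking). The same pooling applied within each centre class yields
regions of directionally biased introgression. Gene overlap uses inclusive
1-based gene coordinates from GFF3 (`gene` features only); BED exports are
0-based half-open.

## Source allele frequencies

Per locus, each source's focal-allele count gets a conjugate Beta posterior
(Jeffreys Beta(0.5, 0.5) prior) with equal-tailed 95% intervals. Loci are
re-oriented so the focal allele is the one common in S1 (p1 ≥ p0; the flip
is recorded, making all downstream quantities invariant to the input VCF's
REF/ALT polarity). Only loci whose S0 and S1 intervals are disjoint —
high-confidence frequency differences — are retained; touching intervals
count as overlapping (conservative, strict inequality).

**Empirical-Bayes pooling (package default).** With small source panels
(tens of individuals) the per-locus plug-in error in p̂₀, p̂₁ is material,
and it leaks into Δwaic as spurious support for the full model — the full
fit has one more dimension along which to absorb an erroneous frequency
endpoint than the v = 1 fit, so plug-in noise inflates the null rate of
negative Δwaic. The retained loci share information: a Beta hyperprior per
source is fitted to the allele counts across loci by beta-binomial maximum
marginal likelihood, and each locus is summarised by its posterior mean
under that hyperprior. The shrinkage uses source genotypes only — admixed
individuals never inform the source frequencies, so locus-specific cline
comparisons cannot be biased toward either model — and reduces the
frequency error by roughly sqrt(1 + (α+β)/n), which brings the null
calibration (measured by the acceptance script and the null-calibration
test) close to the ~5 % a one-extra-parameter comparison predicts. The
unshrunk estimator remains available (`freq_shrink="none"`).

Two alternative treatments were evaluated during development and rejected.
Redrawing p₀, p₁ from their source-only Beta posteriors each iteration
(`freq_update="resample"`, retained as a sensitivity analysis) propagates
the uncertainty but pairs a lagged (v, c) chain with independent frequency
draws, over-penalising the predictive density and over-correcting the null
rate downward. Jointly sampling the frequencies with (v, c) by ancestry
data augmentation is not offered at all: with single-locus panels of a few
hundred allele copies, steepness and the parental frequencies are only
weakly identified jointly (under the null, ln *v* drifts upward with
collapsing effective sample sizes), so the joint treatment needs
multi-locus structure this variant-wise model deliberately does not
assume. Likewise, re-estimating the frequencies from all individuals under
the genome-wide admixture model fits the frequencies to the *reduced*
model's likelihood and biases Δwaic toward the null.

## Synthetic data

The generator is the exact inverse of the fitted model: per test individual
and locus, each of the two allele copies takes S1 ancestry with probability
phi(h<sub>i</sub>; v<sub>l</sub>, c<sub>l</sub>), then the focal allele
with probability p₁ₗ (S1 ancestry) or p₀ₗ (S0); source individuals draw
both copies from their own frequency; genotypes are masked missing
independently. Ancestry is independent per copy — no linkage, no ancestry
tracts, no selection dynamics — because the cline model itself treats
copies as independent observations. Passing tests therefore demonstrate
correct inference *under the model's own assumptions*; they say nothing
about robustness to LD between loci, ancestry-tract structure, genotyping
error or reference bias in real resequencing data.

Defaults (all configurable): 20 + 20 source and 200 admixed individuals;
divergent sources p₀ ~ U(0, 0.2), p₁ ~ U(0.8, 1.0) with an optional
uninformative fraction; hybrid indices uniform on (0.2, 0.95), matching a
hybrid swarm with no near-pure S0 individuals; 8 % short indels (so the
variant-type comparison has both classes); 1 % missing genotypes; barrier
loci as blocks of (fraction, ln *v*, *c*), optionally clustered at 5-kb
spacing to exercise region pooling. An ADMIXTURE-style K-column Q matrix
and a two-sire 1-Mb crossover map (designated hotspot bins and zero-count
coldspot runs on a positive Poisson background) can be emitted alongside.

## Calibration and recovery experiments

Two canned protocols (`clinemap.experiments`) back the quoted numbers:

- **Null calibration** — 2000 loci simulated with *v* = 1, *c* = 0.5
  (p₀ ~ U(0, 0.1), p₁ ~ U(0.9, 1.0); 200 test individuals, h ~ U(0.1, 0.9);
  20 per source), full pipeline, then the fraction of loci with
  Δwaic < −2. For a one-extra-parameter comparison the asymptotic
  expectation is P(χ²₁ > 4) ≈ 4.6 %; residual plug-in noise in ĥ and p̂
  leaves the measured rate slightly above that. The SCV criterion fires on
  essentially no null loci.
- **Recovery study** — hybrid indices from a 20 000-locus, almost entirely
  neutral panel; clines fitted on 100 loci at ln *v* = 2.7, 60 at 2.5, a
  clustered block of 15 at 2.7, and 600 neutral loci. The large estimation
  panel mirrors real analyses (millions of pruned variants) and matters:
  noise in logit(ĥ) near the centre smooths the near-step transition of a
  steep cline and attenuates recovered steepness, so small estimation
  panels understate both ln *v* and SCV power. At the study's panel size
  the suite measures essentially unbiased ln *v* recovery and ~85–90 %
  detection of ln *v* = 2.7 loci at the default SCV thresholds.

Test problem sizes are chosen to keep each suite run in minutes while
leaving the statistical criteria comfortably determined; the experiment
functions scale to larger panels unchanged.

## Association statistics

Weir & Cockerham's multi-population θ is computed per locus from
per-population allele frequencies and observed heterozygosities (missing
genotypes dropped per locus per population; estimates clamped at 0 in a
separate column; loci informative in fewer than two populations are NaN).
The steepness–differentiation association uses a one-way ANOVA of ln *v*
across FST bins (default 0.05-wide bins with a terminal > 0.4 bin — the
binning is a display choice, configurable) plus a Pearson correlation.
Variant-effect regression is OLS of ln *v* on the most-severe consequence
category, reported in the no-intercept (cell-means) parameterisation with
95 % CIs, the overall F from the equivalent with-intercept model;
categories below 1000 variants are dropped. Variant type is SNP iff both
alleles are single bases, indel iff lengths differ; equal-length multi-base
substitutions are excluded (logged); the type comparison is a two-sided
Mann–Whitney U with tie correction. Recombination categories follow the
two-sire convention — hotspot: bin above mean + 2.5 SD in *both* sires (or
an explicit list); coldspot: inside a run of ≥ 3 zero-count 1-Mb bins in
*either* sire; hotspot wins conflicts (flagged) — with OLS plus Tukey HSD
contrasts across categories. The centre-class chi-square compares SCV
versus all-variant class counts (2×3 Pearson, df = 2, no continuity
correction); comparing against the non-SCV complement instead is available
behind a flag, since either reading of "unfiltered" is defensible.

## Numerical choices

Probabilities are clamped to [1e−12, 1 − 1e−12] inside likelihoods and
logit(h) uses h ∈ [1e−6, 1 − 1e−6] (hybrid indices) or 1e−9 (cline stage);
boundary behaviour is carried by priors, not point masses. ESS is
FFT-autocovariance based with Geyer's initial monotone positive-sequence
truncation (cross-checked against arviz); the Geweke z compares the first
10 % and last 50 % segment means with ESS-deflated standard errors. All
printed thresholds are applied with their stated comparison operators
(strict > 0.99 ancestry; ≥ 95 % call rate; strict SCV thresholds; < 50 kb
gaps; inclusive centre-class boundaries). Chains are reproducible from
(seed, data); the pipeline manifest records config, input checksums and
per-stage counts.

## Known limitations

Hybrid indices and source frequencies enter the cline stage as plug-ins;
full uncertainty propagation is limited to the resample option. WAIC
differences carry Monte-Carlo noise at the default chain lengths, which
slightly inflates threshold exceedances. The grouping
supports one S0 and one S1 cluster at a time (run twice for two taurine
definitions, then `compare_approaches`). No BCF/tabix, no multi-allelic
splitting, no genotype likelihoods. The LD thinning utility is a greedy
pairwise-r² scan, not a VIF-based pruner.
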