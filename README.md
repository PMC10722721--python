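# clinemap

Bayesian genomic-cline analysis of admixed populations: from a multi-sample
VCF and an admixture Q matrix to per-locus cline steepness and centre
estimates, WAIC-based detection of variants with restricted introgression,
pooled candidate regions, and the downstream association statistics
(variant effects, multi-population FST, recombination categories).

## The problem

When two divergent populations (S0 and S1 — e.g. indicine and taurine
cattle, or any pair of hybridising lineages) have been exchanging genes,
most of an admixed genome simply tracks the genome-wide mixture proportion.
Loci that do not — where foreign ancestry penetrates much more slowly than
the genome-wide average — are candidates for genomic incompatibilities or
selection against introgression. `clinemap` locates them with Fitzpatrick's
logit-logistic genomic cline: given an individual's hybrid index
*h* ∈ [0, 1] (proportion of the genome from S1), the probability that an
allele copy at locus *l* is of S1 ancestry is

    phi(h; v, c) = logistic( v · (logit h − logit c) ),

so each copy is the focal allele with probability
`phi·p1 + (1−phi)·p0`, where *p₀*, *p₁* are the source allele frequencies.
Steepness *v* > 1 means restricted gene flow (*v* = 1 is neutral); centre
*c* ≠ 0.5 means introgression biased toward one ancestry. Per locus, a full
fit of (ln *v*, logit *c*) is compared with a *v* = 1 reduced fit by the
widely applicable information criterion; Δwaic = waic(full) − waic(reduced)
below −10 together with ln *v* > 2.3 defines a *steep cline variant* (SCV),
and SCVs within 50 kb of each other pool into candidate regions of
restricted introgression.

It is aimed at population-genomics practitioners who have run ADMIXTURE
(or equivalent) on resequencing data and want variant-level introgression
mapping with calibrated uncertainty, plus a fully synthetic test bed.

## Worked example

The numbered scripts under `analysis/` run a complete study on synthetic
data with known truth (outputs under `results/`):

```bash
python analysis/01_simulate.py        # hybrid zone: VCF, Q matrix, truth
python analysis/02_run_pipeline.py    # grouping → h → clines → SCVs → stats
python analysis/03_null_calibration.py
python analysis/04_recovery_power.py
python analysis/05_compare_sensitivity.py
```

`01` writes a panel of 240 individuals (20 + 20 sources, 200 admixed) at
4000 loci, 95 of them true barrier loci. `02` then prints:

```
samples: 240 (S0 20, S1 20, test 200)
loci: 4000 after call-rate filter, 3646 with disjoint source CIs
SCVs: 61; regions: 1 (by centre class: {'S1_biased': 0, 'unbiased': 1, 'S0_biased': 0})
SCVs within genes: 13.1%
of 95 true barrier loci, 61 called SCV; 0 SCVs are false calls
```

i.e. 64 % of the true barrier loci (a mixture of ln *v* = 2.7 and harder
ln *v* = 2.5 loci with shifted centres) are recovered as SCVs with zero
false positives among ~3550 neutral loci, and the one pooled region is the
simulated clustered block (15 steep loci at 5-kb spacing, unbiased
centre). `03` checks the mild support threshold's calibration under the
null (every locus *v* = 1):

```
2000 null loci; hybrid-index RMSE 0.0077
delta-waic < -2 : 6.30% of loci (~5% expected for a one-parameter comparison)
SCV criterion    : 0.00% of loci
```

`04` measures recovery with hybrid indices from a 20k-locus neutral panel
(ln *v* = 2.7 loci: recovered mean 2.83, 89.6 % pass the SCV thresholds;
0 % of null loci do), and `05` re-fits everything with source-frequency
uncertainty propagated ("resample" mode): 58 of 61 SCV calls are shared
between the treatments and ln *v* correlates at 0.98, so the calls are
robust to the frequency plug-in.

The same machinery is available programmatically:

```python
import clinemap as cm

gm          = cm.read_vcf("genotypes.vcf")
q           = cm.read_qmatrix("run.Q", "samples.txt")
assign      = cm.assign_populations(q, s0_cluster=0, s1_cluster=1)  # >0.99
gm          = cm.filter_call_rate(gm, 0.95)
gm, freqs   = cm.estimate_source_freqs(gm, assign)       # Beta posteriors
freqs, gm   = cm.filter_ci_overlap(freqs, gm)            # disjoint 95% CIs
freqs       = cm.eb_shrink_freqs(freqs)                  # pool across loci
hyb         = cm.esth(gm, freqs, assign, seed=1)         # hybrid indices
full        = cm.fit_clines(gm, freqs, hyb, assign, seed=2)
reduced     = cm.fit_clines(gm, freqs, hyb, assign, fix_v=True, seed=3)
merged      = cm.compare_models(full, reduced)           # adds delta_waic
scv         = cm.identify_scv(merged)                    # ln v>2.3, Δwaic<−10
regions     = cm.pool_regions(scv)                       # <50 kb gaps, ≥10
```

or through the CLI (`clinemap simulate`, `clinemap run-all --config
cfg.yaml`, `clinemap compare`). `docs/methods.md` documents the model,
priors, samplers, the empirical-Bayes frequency pooling and the
calibration experiments.

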