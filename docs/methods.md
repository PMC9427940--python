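# Methods

## Model

For each rare variant *v* (within-sample MAF < 0.1%) the endophenotype
*y* is modelled additively in the alternate-allele dosage *g<sub>v</sub>*:

```
y_i = α + β_v g_iv + X_i γ + ε_i
```

where *X* holds age, sex, the trait's clinical covariates and the first
12 principal components of ancestry (a 4-PC preset is available for
single-ancestry sensitivity analyses). β<sub>v</sub> is the variant's
effect size in trait units per allele; inference is by the model
t-statistic. By default ε is i.i.d. and the fit is OLS. Optionally a
genetic variance component is added, `cov(y) = σ²_g K + σ²_e I` with *K*
a kinship matrix; the variance ratio is profiled out of the REML
likelihood after an eigendecomposition of *K*, fixed effects then follow
by GLS. With *K = I* this collapses exactly to OLS (tested to 1e−8).
Per-ancestry-group residual variances are not implemented; the single
residual variance is a documented simplification.

Clinical covariate sets per trait: LDL-C — HDL, MI history, statin use;
QTc — beta blocker, calcium channel blocker, MI history, heart failure;
HbA1c — MCV, diabetes medication use. Continuous covariates (HDL, MCV)
are imputed to the observed median, binary histories to "no history".
QTc is the Bazett-corrected QT (QTc = QT/√RR, QT in ms, RR in s), with
ECG-level exclusions (QRS > 120 ms; heart rate < 40 or > 120 bpm,
HR = 60/RR when only RR is given) and participant-level exclusions (WPW,
pacemaker, 2nd/3rd-degree AV block, class I/III antiarrhythmics,
digoxin). Boundary conventions are read literally: QRS 120 is kept, 121
excluded; HR 40 and 120 are kept. ECG- and participant-level exclusions
commute, so their order is irrelevant.

Carrier-level contrasts fit one linear model of *y* on per-category
carrier indicators (plus the same covariates) with non-carriers as the
implicit baseline, then report each category minus the benign-carrier
coefficient with a t-based 95% CI and unadjusted two-sided P. A sample
carrying variants in several categories is assigned its most severe
category (pathogenic > likely pathogenic > conflicting > VUS > likely
benign > benign); the mutually exclusive assignment is a design choice —
a per-category multi-indicator coding would also be defensible — and is
applied identically everywhere.

## Discrimination and thresholds

Discrimination of pathogenic from non-pathogenic (likely benign + benign)
variants uses an unadjusted logistic regression of the label on the
effect size; since the fitted score is monotone in β, the reported AUC is
the rank-based (Mann–Whitney) AUC of β itself, with ties counted ½ and a
DeLong-variance normal CI clipped to [0, 1]. Under perfect separation the
logistic slope diverges (recorded as fitted); the AUC is unaffected.

The "large effect" rule classifies β ≥ *m* · SD(*y*) as evidence of
pathogenicity, default *m* = 0.5, where SD(*y*) is the sample SD of the
raw phenotype in the analysis cohort (not residuals). The comparison is
"≥" on the signed, trait-raising β; an absolute-value mode exists for
traits lowered by disease alleles. Sensitivity, specificity, PPV and NPV
come from the 2×2 table over the asserted pathogenic vs likely-benign/
benign sets only (VUS/conflicting excluded from the negatives), with Wald
binomial CIs; empty margins yield NaN plus a note rather than an error.
The sweep grid default is {0.25, 0.5, 0.75, 1, 1.25, 1.5, 2} SD.

The Hardy–Weinberg filter uses the standard exact conditional test (no
mid-P): the P value sums the probabilities of all heterozygote counts no
more probable than the observed one, given the allele counts; the
implementation normalizes log-probabilities over the conditional support
and tolerates a 1e−12 relative slack when comparing probabilities for
tie inclusion. Sample-outlier means and SDs are computed once on the
input table (not iteratively), a zero-SD metric yields no outliers, and
the outlier screen is applied to the whole table rather than per
ancestry group.

## PFI

PFI = (tools calling the variant damaging) / (tools with a prediction),
over 22 qualitative tools (hit = "D"; the MutationAssessor slot hits on
"H" only, not "M") and 9 quantitative rank-score tools (hit = score
strictly > 0.90 on the 0–1 rank scale). Multi-transcript strings such as
"D;T" hit if any sub-prediction hits. A variant with no available tool
has undefined PFI and is flagged, not scored 0. Group summaries report
median and quartiles with linear interpolation between order statistics.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
rare variants placed in gene panels with per-category true effects
specified in trait-SD units; covariates with realistic baselines (age
~ N(57, 8.1); sex ~ Bernoulli(0.5); trait-specific clinical covariates,
e.g. HDL ~ N(56, 13), MCV ~ N(91.2, 4.5); 12 small-variance PCs with
optional confounding loadings); phenotype = intercept + covariate effects
+ Σ dosage·effect + N(0, noise_sd). Default noise SDs are 33.4 mg/dL
(LDL-C), 23.8 ms (QTc) and 0.62% (HbA1c), chosen so that 0.5 trait SD
corresponds to thresholds of realistic magnitude for each trait. True
effects convert from SD units to trait units via the noise SD (rare
variants contribute negligibly to the trait variance); a noise-free
config falls back to a unit conversion so that generative identities
remain exercisable. Default category means are 0.9 SD (pathogenic),
0.5 SD (likely pathogenic), 0.15/0.1 SD (VUS-like/conflicting-like) and
0 (benign side); the benign mean of zero is a modelling choice, as the
empirical distribution of non-pathogenic effects is not characterized.

Carriers are heterozygous by default (hom-alt carriers opt-in), placed by
drawing a minor allele count uniformly from {1, …, mac_max} where mac_max
is the largest count with MAF strictly below the ceiling; a config whose
sample size admits no carrier is rejected with a message naming the
constraint. Assertion labels mask the truth to VUS/conflicting/absent at
configured fractions, then flip surviving labels across the
pathogenic/benign axis at the misclassification rate. Predictor matrices
draw damaging calls per tool with probability
sigmoid(intercept + slope·|effect in SD|), defaults (−1.5, 3.0), placing
quantitative hits uniformly in (0.9, 1] and misses in [0, 0.9). Raw call
tables are clean by construction and then corrupted one mode at a time
(low/high depth, low GQ, low PL, allele imbalance) at configured rates,
with the injected mode recorded.

Not emulated: linkage disequilibrium, ancestry admixture, sequencing
reads, genotype-calling error correlated across samples, realistic
site-frequency spectra, and the empirical effect distribution of real
ClinVar categories. Passing tests therefore demonstrate correctness of
the estimators and classifiers under the assumed generative model, not
the field performance of the threshold rule on real cohorts.

All randomness flows from one config seed; stage-level generators are
derived via CRC-32-salted seed sequences, so outputs are byte-identical
across reruns (fixed float formatting in all writers).

## Reference study sizes

The recovery study uses n = 5,000 samples and a 200-variant panel with
point effects {0, 0.5, 0.9} SD over 20 seeds for testing (10 seeds in the
acceptance script), and a 20,000-sample three-gene cohort for nomination
and PFI summaries — sizes chosen to make Monte-Carlo error small relative
to the quantities checked while keeping a full run in seconds.

## Known limitations

- Marginal per-variant regressions contaminate each other slightly when
  panel variants share the phenotype (bounded by |other effect| ×
  carriers / n); the joint fit is exact and used as the test oracle.
- The 8-SD sample-outlier filter is single-pass; on pathological inputs
  with borderline outliers a second application can remove more samples.
- Wald proportion CIs are anti-conservative at very small counts; the
  AUC CI is asymptotic (DeLong).
- Low-complexity flags, genetic sex and duplicate flags are inputs: their
  upstream inference (repeat annotation, X-heterozygosity, KING) is out
  of scope.
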