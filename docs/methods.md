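# Statistical methods

This note documents the models, the estimator corrections, the synthetic
data generator and its parameter choices, and the known limits of the
analysis. Notation: two groups A and B with $n_g$ replicates each; features
are CpG loci (5mC), strand-specific CCGG tags (5hmC) or genes (RNA).

## 1. Differential methylation (beta-binomial Wald test)

Per CpG locus and sample, the methylated read count $m_s$ given coverage
$c_s$ is beta-binomial with mean $\mu$ and dispersion $\varphi$:

$$\mathrm{Var}(m_s) = c_s\,\mu(1-\mu)\,\bigl(1 + (c_s - 1)\varphi\bigr).$$

**Group means.** Coverage-weighted: $\hat\mu_g = \sum m_s / \sum c_s$, with
variance

$$\mathrm{Var}(\hat\mu_g) = \mu(1-\mu)\,\frac{\sum_s c_s\bigl(1+(c_s-1)\varphi\bigr)}{(\sum_s c_s)^2}.$$

The variance plug-in uses a lightly regularised mean,
$(\sum m + 0.5)/(\sum c + 1)$, so the standard error is positive at boundary
loci.

**Dispersion.** Per-locus method of moments on the residuals of the sample
proportions around their *own group's* mean (group-wise moments, so a
genuinely differential locus does not inflate its own dispersion), solved
from

$$E\Bigl[\sum_s (\hat p_s - \hat\mu_g)^2\Bigr] =
\tfrac{n_g - 1}{n_g}\,\mu_g(1-\mu_g)\sum_s\bigl(\tfrac1{c_s} + \varphi(1 - \tfrac1{c_s})\bigr),$$

floored at $10^{-4}$, capped at $0.5$, then shrunk toward the 10 %-trimmed
mean across loci with weight $w = n_\ell/(n_\ell + 4)$ ($n_\ell$ = samples
meeting the coverage floor). Identical loci are a fixed point of the
shrinkage; an outlying locus is pulled toward the prior but stays between
prior and raw estimate.

**Test.** $z = \hat\Delta/\widehat{SE}$, $\hat\Delta = \hat\mu_B - \hat\mu_A$,
referred to the standard normal; Benjamini–Hochberg adjustment
(statsmodels); a locus is a DML when $p_{adj} < 0.05$ **and**
$|\hat\Delta| \ge 0.10$ (ten percentage points). Loci with coverage below 5
in any sample of the comparison are excluded before adjustment.

## 2. Differential counts (negative-binomial Wald test)

Used identically for 5hmC tags (DHML) and RNA genes (DEG). Counts
$K_{fs}$ are NB with mean $sf_s\,\mu_f$ and variance
$\mu + d\,\mu^2$ on the normalised scale.

**Normalisation.** Median-of-ratios size factors (features positive in all
samples; total-count fallback otherwise), rescaled to geometric mean 1.
Rescaling all libraries by constants with geometric mean 1 leaves the
normalised means — hence all effect estimates — exactly unchanged.

**Dispersion.** Group-wise method of moments on normalised counts
($s^2_g \approx \mu_g\,\overline{1/sf} + d\,\mu_g^2$), floored at $10^{-8}$,
then shrunk with weight $w = n/(n+4)$ toward a mean-dispersion trend
$d(\mu) = a/\mu + b$ fitted by least squares **on the raw scale** with
$a, b > 0$ (exp-parameterised). The raw scale matters: at small $n$ the
method-of-moments estimates have a coefficient of variation near 1, and a
log-scale fit is pulled far below the true trend by Jensen's inequality,
which made the Wald test measurably anticonservative (null
$p<0.05$ fraction 0.067 instead of 0.05 at $n=3$/group). With fewer than 10
usable features the trend falls back to the global mean (with a warning).

**Test.** Wald statistic on the log2 scale,
$z = (\log_2\hat\mu_B - \log_2\hat\mu_A)/\widehat{SE}$ with
$\widehat{SE}^2 = \sum_g \mathrm{Var}(\bar q_g)/(\mu_g \ln 2)^2$; the
plug-in group mean is floored at "one read in the whole group"
($1/\sum_g sf_s$) so an all-zero group yields a finite, conservative SE.
The reported `log2fc` uses a pseudo-count of 0.5 on both group means —
point estimate only, never inference. Significance: $p_{adj} < 0.05$ and
$|\mathrm{log2fc}| \ge 1$ (two-fold). All-zero features are excluded.

## 3. Plug-in dispersion noise (both tests)

A Wald denominator built from an *estimated* dispersion is correlated with
the numerator's sampling noise, inflating type-I error at small $n$. Both
tests absorb this to first order:

$$\widehat{SE}^2_{corr} = \widehat{SE}^2\Bigl(1 + \frac{D^2\,\widehat{\mathrm{Var}}(\hat d)}{\widehat{SE}^4}\Bigr),
\qquad D = \partial\,\widehat{SE}^2/\partial d,$$

with $\mathrm{Var}(\hat d)$ from the chi-square approximation
$\mathrm{Var}(s^2) \approx \sigma^4 (2/\mathrm{df} + \kappa/n)$, including
the NB excess kurtosis $\kappa = 6/r + p^2/(r(1-p))$ for the count models,
and scaled by the squared shrinkage weight. Measured null $p<0.05$
fractions after both corrections (5000 loci / 1000 features, $n=3$/group):
beta-binomial mean 0.053, NB mean 0.054 across 12 seeds.

## 4. Gene annotation

Significant point loci are extended by ±2 kb into half-open intervals
$[\max(0, pos - f),\ pos + f + 1)$, merged when overlapping or book-ended,
and clipped (with a warning) at chromosome ends. A gene is hit when a merged
region overlaps its body by ≥ 1 bp. Per gene, the direction is the majority
sign of the contributing loci's effects (methylation difference for 5mC,
log2 fold change for 5hmC); an exact tie records both directions. The two
strands of a CCGG site are always distinct features and are never merged
before extension.

## 5. Patterns, trackability, switching

A detected gene at one stage carries one of the **7** non-empty subsets of
{RNA, 5mC, 5hmC} in canonical order (RNA=1, 5mC=2, 5hmC=3, RNA+5mC=4,
RNA+5hmC=5, 5mC+5hmC=6, all=7). The undifferentiated stage is read from the
between-line contrast of undifferentiated samples; each differentiated
stage, per environment, from the union of the per-line undiff-vs-environment
comparisons. Transition numbering is deterministic: undiff-only genes keep
1–7, trackable transitions occupy $7 + (u-1)\cdot 7 + d \in [8, 56]$,
diff-only genes $56 + d \in [57, 63]$.

A **reciprocal switch** requires unambiguous single directions in *both*
environments: `gain5mC_loss5hmC` means 5mC gain + 5hmC loss under Mac-CM
with 5mC loss + 5hmC gain under DM; `gain5hmC_loss5mC` is the mirror image.
Any other combination — a missing modality, a missing environment, or a
tied direction — is `none`. The classes are mutually exclusive by
construction.

## 6. Synthetic data generator

The generator is the package's study-condition model; its defaults were
chosen once, for realism, and are not tuned to test outcomes.

| Parameter | Default | Rationale |
| --- | --- | --- |
| `mean_coverage` | 30 | typical reduced-representation per-CpG depth |
| `bb_dispersion` | 0.1 | typical RRBS biological dispersion between replicates |
| `nb_dispersion` | 0.1 | typical bulk count-data dispersion |
| `baseline_mu` | 0.4 | CpG-dense regions are partially methylated |
| `planted_delta` | 0.30 | a strong but realistic methylation shift |
| `planted_lfc` | 2.0 | four-fold, comfortably above the two-fold call threshold |
| `frac_true` | 0.1 | a minority of features is differential |
| `mean_log_sigma_rna` / `_tags` | 1.0 / 0.5 | lognormal spread of expression / tag abundances |
| replicates | 2 per (line, condition) | the study design being modelled |

RRBS: NB coverage, beta-binomial methylated reads. RRHP/RNA: NB counts;
RNA adds per-sample size factors drawn from $U[0.5, 2]$ and recorded in the
truth. `simulate_dataset` plants per-comparison effects on disjoint gene
sets, assigns half of the TF genes reciprocal 5mC/5hmC switch effects
(opposite pairing in DM vs Mac-CM, in both lines), and applies line-contrast
effects to *all* samples of the second line so within-line comparisons stay
null. Every planted effect is recorded in a JSON-round-trippable
`PlantedTruth`.

**Realism limits.** Loci are exchangeable given their gene (no local
correlation along the chromosome); coverage is independent of methylation
state; effects are constant shifts, not mixtures; chromosome structure is a
uniform gene grid with randomised offsets. These idealisations make planted
truth unambiguous and power analytically checkable, at the cost of
understating the heterogeneity of real libraries.

## 7. Power limits at the study design

At $\Delta = 0.30$, coverage 30, $\varphi = 0.1$, $n = 3$/group, the *oracle*
standard error of $\hat\Delta$ is

$$SE = \sqrt{2\,\mu(1-\mu)\Bigl(\tfrac{1}{\sum c} + \varphi\,\tfrac{(c-1)/c}{n}\Bigr)} \approx 0.144,$$

so even with the true dispersion the expected Wald $z$ is ≈ 2.1 — far below
what sensitivity 0.80 after BH and the $|\Delta| \ge 0.10$ filter requires
($\varphi \lesssim 0.005$ would be needed). Measured DML sensitivity at
these conditions is ~0.15–0.25. Reciprocal-switch recovery compounds this
across four line × environment comparisons at $n=2$/group, giving ~0.3–0.45
sensitivity (with zero false switch calls in our runs). These are properties
of the design, not of the estimators: the corresponding acceptance
assertions are kept at their stated thresholds and fail honestly. DEG and
DHML recovery at log2FC = 2 reaches sensitivity ≈ 0.9 at empirical
FDR ≈ 0.05–0.08.

## 8. Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; the pipeline summary is byte-identical across runs with the
  same seed (timing fields are stripped, numpy scalars converted, keys
  sorted).
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  clustering to `scipy.cluster.hierarchy` (average linkage, Euclidean);
  Fisher's exact test (used as an independent cross-check of the
  beta-binomial p-value ranking) to `scipy.stats`.
- PCA is a feature-centred SVD; sample scores $U\Sigma$, reproducible up to
  a sign per component.
- Coordinates are 0-based half-open everywhere (BED convention); feature
  ids are `chrom:pos:strand`.
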