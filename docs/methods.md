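# Methods

This note documents the models behind each stage of `rhfsig`, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices that affect results.

## Differential expression (deg_screen)

Counts are modeled as negative binomial with mean–dispersion
parameterization Var(K) = μ + αμ². Samples are put on a common scale with
median-of-ratios size factors (the geometric-mean reference is computed
over genes with all-positive counts; if none exist the factors fall back to
library-size ratios). Per-gene dispersion is estimated by method of moments
from the pooled within-group variance of normalized counts, floored at
1e-4, and shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ. The trend is fitted
to 10%-trimmed means of the per-gene estimates within up to 20
mean-expression quantile bins: raw moment estimates at 6 replicates are
heavy-tailed, and an unbinned least-squares fit overestimates the intercept
badly enough to make the test visibly conservative. With the binned fit,
effect-free simulations put the p ≤ 0.01 rate within three binomial
standard errors of 0.01 (checked in the acceptance suite at 6,000 genes).

The test statistic is a Wald z on the log₂ ratio of adjusted group means
with delta-method standard error √[(1/μ_A + α)/n_A + (1/μ_B + α)/n_B]/ln 2
against a standard normal. Genes with zero counts everywhere get p = 1 and
log₂FC = 0. The engine is deliberately simple and fully specified; it is
cross-checked against DESeq2 (via pydeseq2) in the test suite, where the
two agree to Spearman ρ > 0.95 on p-values with identical effect signs
among significant genes. Shrunken LFCs, independent filtering and outlier
replacement are intentionally out of scope.

Reported log₂ fold changes use mean RPM with a 0.5-RPM pseudocount
(configurable) to avoid infinities; the Wald statistic itself uses the
adjusted means.

Filter boundaries follow the stated rules literally: the two-fold cut is
inclusive (|log₂FC| ≥ 1), the disease-mean cut strict (> 50 RPM), the
p cut inclusive (≤ 0.01). The rodent filter uses raw p by default (a flag
switches to BH-adjusted); the human contrast filter requires BH-adjusted
p < 0.05, average count > 5 and |log₂FC| > 0.585, all strict. Whether the
decompensated DEG sets should also exclude contralateral DEGs is ambiguous;
they are taken as affected-ventricle DEGs without exclusion, which is the
reading consistent with the published partition arithmetic
(121 + 160 − 57 = 224).

## Pattern clustering (pattern_clusters)

Per-gene condition means are standardized with the sample standard
deviation; zero-variance rows cannot be standardized and are excluded and
reported rather than assigned arbitrarily. k-means (scikit-learn, k-means++
seeding, best of 10 restarts by inertia) on standardized rows is equivalent
to one-minus-Pearson-correlation clustering because
‖zᵢ − zⱼ‖² = 2(n−1)(1 − rᵢⱼ) for standardized rows; the identity is
asserted numerically in the tests. Cluster ids are canonicalized by
descending size, then lexicographically smallest member, because raw
k-means labels are arbitrary and figure-specific numbering is not
reproducible. Rows are sorted canonically before fitting so assignments do
not depend on input order.

## Clinical risk and severity (esc_rank)

Risk classification uses fixed parameter bands (low: CI ≥ 2.0 L/min/m²,
NT-proBNP < 300 ng/L, TAPSE/sPAP > 0.32 mm/mmHg; high: CI < 2.0, > 1,100,
< 0.19) with a 2-of-3 rule; a patient with two low-band and one high-band
parameter is classified by the majority. Missing parameters are an error —
no imputation.

"Equal weighting" of the three parameters for the severity rank is
implemented as the unweighted mean of per-parameter midranks (CI and
TAPSE/sPAP ascending, NT-proBNP descending, so higher rank = healthier),
re-midranked. No formula is published for this step; the rank-average is
the simplest equal-weight scheme that is invariant to units and to any
strictly monotone transform of a raw parameter (a property the tests
assert).

The correlation screen computes Pearson r of each gene against the
composite rank with a two-sided t-test (n − 2 df). Selection uses strict
|r| > 0.3 and inclusive p ≤ 0.01, unadjusted by default (BH by flag). At
n = 71 the two cuts nearly coincide (|r| = 0.3 corresponds to p ≈ 0.011),
so the null selection rate is the nominal 1%. Constant genes are flagged
and never selected. Negative r means higher expression in sicker patients —
the orientation in which most signature genes appear.

## Cross-species signature (signature)

Ortholog pairs are reduced to a 1:1 map (lexicographically first partner on
either side, dropped pairs reported) before intersection. The Venn
partition of the mapped rodent set against the two human lists is a
disjoint cover; unmapped rodent genes are reported separately. Fisher
overlap tests are one-sided hypergeometric upper tails — the direction of
interest is enrichment — and the universe (genes expressed in the human
baseline cohort) must be supplied explicitly; there is no silent default.
The ECM/secreted vs non-ECM split annotates core genes against any
supplied matrix/secretome set; induced interaction edges are kept at
confidence score strictly greater than 0.4, undirected, self-loops removed.

## Enrichment (enrichment)

ORA restricts every set to the universe and excludes restricted sizes
outside [5, 2000] before testing; p-values are hypergeometric upper tails,
BH-adjusted across tested terms. The term-collection filter keeps terms
with p < 0.01, overlap ≥ 3 and enrichment factor (observed/expected)
strictly > 1.5. Kappa-similarity clustering of terms is out of scope; a
best-p merge utility stands in for multi-list merging.

GSEA sorts genes by decreasing statistic (ties broken by gene id for
reproducibility), accumulates hit increments ∝ |stat|^w (w = 1 by default;
w = 0 gives the unweighted KS statistic) and uniform miss decrements, and
takes the running-sum extremum as ES. The null permutes gene labels at
fixed set size (the convention of the clusterProfiler/fgsea family, which
matches how such pseudo-bulk analyses are normally run; phenotype
permutation is not offered). The permutation p is the one-sided exceedance
among same-sign null scores with the +1 correction, which keeps the
empirical type-I error at the nominal level (checked over 200 replicates);
NES divides ES by the mean |null ES| of the matching sign, falling back to
all permutations when one sign is empty. The extremum search evaluates
only the O(set size) candidate points just before/after each hit, which is
exact; tests compare it against a full running-sum enumeration. The number
of permutations (default 1,000; minimum 100) and the weight are exposed as
parameters.

## Pseudo-bulk (pseudobulk)

Cell-level counts are summed per (sample, cell type) — exact, additive and
order-invariant. The base-mean filter removes genes whose plain mean raw
pseudo-bulk count across the contrast samples is strictly below 5
(size-factor-adjusted means by flag). Ranking for GSEA reuses the NB Wald
engine on the pseudo-bulk profiles and returns the signed z. Dot-plot
summaries report the fraction of expressing cells and the mean of
log1p(counts-per-10k) per (cell type, condition, gene); the per-cell
normalization for "mean expression" is not standardized anywhere, and
counts-per-10k log1p is the common single-cell convention.

## Proteome (proteome_integration)

Abundances are log₂ transformed and width normalized: each sample is
centered on its median and scaled so its interquartile range equals the
median IQR across samples. This is a location–scale proxy for the named
desktop procedure, whose exact formula is not published; a raw passthrough
is available, and a single-sample matrix is only log-transformed. The
valid-value filter keeps proteins with ≥ ceil(0.75 × group size) valid
values in at least one group — six of eight at the default design. DEPs
are two-sided two-sample t-tests at −log₁₀ p ≥ 1.3 (inclusive, i.e.
p ≤ 10^−1.3 ≈ 0.0501), raw p by default with BH optional; proteins with
fewer than two valid values in a group are skipped and reported.
mRNA–protein concordance is Pearson r/r² with the least-squares slope and
the F-test p for zero slope (identical to the regression t-test for a
single predictor).

## Synthetic cohorts (synthdata)

The generators exist so every stage is testable without the deposited
data. Design constants mirror the study: six animals per group and
ventricle over groups {Sham-H, Sham-F, PAB-H, PAB-F, AOB-H, AOB-F} × {RV,
LV}; a 17,341-gene rodent universe at 25 million expected reads per
sample; 71 patients over a 16,354-gene expressed universe; eight proteome
replicates per group. No distributional description of the real data is
published, so the distributional defaults are stand-ins chosen to look
like bulk RNA-seq: log-normal gene abundance (log-sd 1.8), NB dispersion
trend α(μ) = 0.05 + 5/μ, log-normal library sizes at CV 0.2 (so
per-million normalization is non-trivial). Planted rodent templates add
log₂ effects per (group, ventricle) cell; unnamed cells carry effect 0.

The human cohort draws a latent severity uniform on [0, 1]; cardiac index
and TAPSE/sPAP decrease linearly in severity with Gaussian noise
(truncated at physiological floors), NT-proBNP increases log-linearly from
100 to 3,000 ng/L with log-normal noise — keeping values positive.
Planted genes respond linearly to the centered severity rank with slope
±3 counts/rank on baselines of 150–400 counts, which yields a population
|r| near 0.6 at n = 71. The single-cell generator plants a disease
program in one cell type for the disease-condition samples on top of mild
constitutive cell-type programs.

One global seed fans out to per-simulator child seeds by fixed offsets, so
sub-simulations are independently reproducible. All simulators are
deterministic given (config, seed).

What the synthetic data do **not** emulate: batch effects, sample
contamination and cell-type impurity, GC/length biases, read-level
artifacts, realistic gene–gene correlation, informative (non-MCAR)
proteome missingness, and clinical confounders (age, sex, comorbidity).
Passing tests demonstrate that the statistics behave as specified under
the stated model — calibrated nulls, recovery of planted effects — not
that they are robust to real-data pathologies outside that model.

## Problem sizes in the test and acceptance suites

Null calibrations use 6,000 genes (DEG rate), 12,000 genes × 71 patients
(correlation screen), 200 replicates × 199 permutations (GSEA type-I) and
4,000 proteins (DEP rate). Recovery suites use 20 replicates of 800-gene
rodent cohorts (40 planted four-fold genes), 20 replicates of 2,000-gene
patient cohorts with 300 planted severity genes, and 10 replicates of
1,000-cell two-cell-type cohorts. The planted patient cohorts for the
recovery suite use balanced positive/negative planting: a strongly
unbalanced planted mass shifts library totals monotonically with severity
and would leak a compositional correlation into every null gene, so the
balanced design measures the screen rather than the normalization. That
compositional sensitivity is a real property of per-million and
ratio-based normalization and is documented here as a known limitation —
the screen operates on median-of-ratios-normalized counts, which bounds
but does not eliminate the effect.

## Known limitations

* The NB Wald engine is a documented stand-in for a full shrinkage-based
  DE framework; it has no outlier handling and modestly lower power at
  very small counts.
* The GSEA null permutes gene labels, which ignores inter-gene
  correlation; p-values on strongly co-expressed sets are optimistic, as
  with all gene-sampling nulls.
* Width normalization is an IQR-based proxy; results can differ from other
  implementations of the same idea in the tails.
* The composite severity rank treats the three clinical parameters as
  exchangeable after ranking; alternative weightings are not explored.
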