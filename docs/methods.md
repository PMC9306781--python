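# Methods

## Overview

`pleioscan` quantifies *parallel genomic divergence* across replicate
ecotype pairs (e.g., independent stream–lake or benthic–limnetic pairs of
threespine stickleback) and asks whether the genomic windows that diverge
in parallel carry more *pleiotropy* than the rest of the genome. Pleiotropy
is proxied two ways: the number of distinct mapped QTL traits per window,
and the mean coexpression connectivity (kTotal) of the genes in a window.
Per-window covariates — gene density, recombination rate and a
synonymous-substitution-rate (dS) mutation proxy — are carried along so
that a pleiotropy signal can be distinguished from these confounders.

All statistics live on one shared coordinate system: a fixed 50-kb tiling
of the genome with 0-based half-open windows. Point features (SNPs) map to
the window containing their position; interval features (QTL, genes) map
to the window containing their midpoint, with a boundary midpoint going to
the right window. Using a single assignment rule everywhere keeps every
annotation commensurable.

## Differentiation scan

Per-SNP differentiation uses the Weir–Cockerham (1984) theta estimator for
two populations. For each biallelic site we compute the among-population
variance component `a` and the within-population components `b + c` from
diploid genotype counts; theta-hat is `a / (a + b + c)`. Negative
estimates are retained unclipped. Sites whose denominator is exactly zero
(monomorphic across both populations) carry no information: they are
flagged non-variable and never count toward window totals.

Window F_ST is the **ratio of sums**: sum of per-site numerators divided
by the sum of per-site denominators over the window's variable sites. This
is less noisy than averaging per-site ratios and makes window values
additive under concatenation of site lists. Windows with fewer than
`min_sites` (default 3) variable sites report a missing F_ST.

Missing genotypes are excluded from the per-site counts (the handling of
partially missing sites is not standardized in this literature; exclusion
per site is the package's documented, configurable choice).

## Outlier calling and parallelism

Within each pair, outlier windows are those whose F_ST lies **strictly
above** the empirical 95% quantile (type-7 / linear-interpolation
convention) of that pair's defined window values; ties at the threshold
are excluded. The strictness and quantile convention are documented
dialect knobs — "top 5%" does not pin down tie behavior, so the package
fixes one reproducible rule and exposes the quantile as a parameter.

A window is **parallel** when it is an outlier in at least `min_pairs`
pairs (default 2) and **nonparallel** otherwise (outlier in one pair or
none). A window missing in a pair contributes neither to that pair's
quantile nor to its outlier count, so windows with data in only two pairs
can still be called parallel.

The continuous companion metric ranks each pair's window F_ST values
(average ties, missing kept missing) and averages ranks per window across
pairs. It is invariant to any monotone per-pair transform of F_ST, which
is the point: replicate pairs differ in overall divergence magnitude.

## Pleiotropy proxies

**QTL trait counts.** Each QTL record is placed at the midpoint of its
marker confidence interval, falling back to the midpoint of its flanking
markers. Within a window the same trait (whitespace/case-normalized name;
no fuzzy matching) counts once regardless of how many studies mapped it.
Mean PVE is a two-stage average: within trait first, then across traits;
records without PVE drop out of their trait's average and traits with no
PVE at all drop out of the across-trait mean. Windows with **no** QTL
report a *missing* trait count by default rather than zero
(`zero_as_missing=True`): a QTL database records only mapped traits, so
absence of a record is absence of information, and treating the thousands
of empty windows as zeros would swamp the class contrast with
non-observations. The switch is exposed for users who prefer zeros.

**Coexpression connectivity.** Expression preprocessing is
`log2(FPKM + 1)` followed by removal of genes whose log-scale variance
falls strictly below the first quartile of all gene variances (the
low-variance tail is mostly noise; the quantile is a parameter because
"first quantile" is ambiguous in common usage, and a flag allows filtering
on raw-scale variance instead). The unsigned weighted network has
adjacency `|cor(x_i, x_j)|^beta` (Pearson, complete matrices required),
and a gene's total connectivity is `kTotal_i = sum_{j != i} a_ij`. Module
detection is deliberately not implemented: kTotal sums within- and
between-module adjacency, so it is module-independent, and downstream
analysis consumes only kTotal.

The soft-thresholding power beta is chosen where the scale-free topology
fit saturates: for each candidate power we bin connectivity into 10
equal-width bins and regress log10(bin frequency) on log10(mean bin
connectivity); the fit index is the squared correlation, signed negative
when the slope is positive. The smallest power reaching R² ≥ 0.85 wins,
falling back to the argmax, and a user-fixed power overrides selection.
The pipeline default is a fixed beta = 6; on the synthetic data the
diagnostics saturate early, and fixing the power keeps replicate runs
comparable.

Gene kTotal maps to windows by coding-region midpoint and is averaged per
window; windows without genes are missing.

## Covariate tracks

Gene density counts gene midpoints per window; zero is a real value.
Recombination rate interpolates genetic-map cM positions linearly at
window boundaries (rate = ΔcM / window length in Mbp); windows not fully
inside the marker span are missing, and per-chromosome ΔcM over covered
windows conserves total map length to 1e-9. The boundary-interpolation
rule (rather than averaging marker-interval rates) is a documented
dialect. dS arrives as a precomputed per-window track and is joined by
(chromosome, window start); estimating dS is out of scope here.

## Inference

The class contrast is `mean(parallel) − mean(nonparallel)` of a per-window
metric, equivalently the slope of a linear model on a status indicator.
Because the pleiotropy metrics are strongly right-skewed, significance
comes from a label-shuffling permutation null with 10,000 iterations by
default: parallel/nonparallel labels are reassigned uniformly at random
**among windows that carry a metric value** — missing windows are held in
place and never enter either class — preserving the observed number of
parallel labels, and the difference is recomputed per iteration. The
p-value uses the add-one estimator `(1 + #{|null| ≥ |obs|}) / (1 + n_iter)`,
two-sided by default with a one-sided option (the a-priori hypothesis was
directional; sidedness is reported with the result). For small problems an
exhaustive mode enumerates all C(n, k) label arrangements and returns the
exact p-value.

The continuous analysis is the Pearson correlation between a metric and
mean F_ST rank with the usual t-test on n − 2 degrees of freedom.
Restriction flags rerun identical machinery on outlier windows only
(parallel-outlier vs single-pair-outlier) or contrasting any-outlier vs
never-outlier windows.

Class means are reported with standard errors (means ± SE); no
multiple-testing correction is applied across the six metrics — raw
permutation p-values are the deliverable, as is conventional for this
analysis.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes and
carries a ground-truth table for parameter-recovery testing. It does
**not** emulate linkage disequilibrium, demographic history, sex
chromosomes, read-level sequencing noise, or the missingness patterns of
reduced-representation sequencing — so passing recovery tests demonstrate
that the estimators and inference machinery recover implanted marginal
effects, not that the pipeline is robust to those real-data complications.

Default study design: 16 replicate pairs, 24 diploids per population,
5 chromosomes × 25 Mb = 2,500 windows of 50 kb, 5 SNPs per window.

**Divergence** is Balding–Nichols: per SNP and pair, ancestral frequency
p0 ~ Uniform(0.05, 0.95) and population frequencies
Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F = `F_selected` (default 0.5) for
(window, pair) combinations flagged in the truth table and `F_background`
(default 0.05, giving genome-wide window F_ST ≈ 0.06, inside the range
reported for such surveys) elsewhere. Only the marginal F_ST structure
matters to a window scan, so this is the simplest model with a tunable
F_ST expectation. Genotype counts are drawn as
Multinomial(n, (p², 2p(1−p), (1−p)²)) — the exact distribution of n
independent Binomial(2, p) diploids under Hardy–Weinberg sampling.

**Truth classes.** A fraction `prop_parallel` (default 0.12) of windows is
implanted with elevated F in k pairs, k uniform on {2, …, 4} (most shared
outliers in the motivating surveys involve two to four pairs);
`prop_single` (default 0.05) windows get one selected pair; the rest are
background. Two structural facts shaped these defaults. First, with
complete data in all pairs, the 5%-quantile × 16-pair geometry produces a
near-constant ~450 called-parallel windows (~18% of the genome, close to
the ~15% such surveys report) regardless of how many are implanted —
chance-shared outlier windows fill whatever the implant does not. The
implant fraction therefore controls the *purity* of the called class
without changing its observable size, and the default is chosen so that
implanted effects remain detectable through that dilution. Second,
single-pair-implant windows convert to false "parallel" calls at a high
rate (one genuine outlier plus one chance outlier), so their share is kept
modest.

**QTL.** Each window carries QTL with probability 0.34 (≈ the density of
curated QTL across scanned windows in the motivating data set). A
QTL-bearing window receives 1 + Poisson(λ) distinct traits with
λ = `lambda_base` = 0.5 for background/single windows (mean 1.5) and
λ = `pleiotropy_effect`·(1 + λ) − 1 for parallel windows, so class means
scale exactly by `pleiotropy_effect` (default 2 → mean 3.0, the reported
two-fold elevation). PVE is log-normal with median 9% (σ = 0.5 on the log
scale), matching reported nonparallel means near 9.5%. Confidence
intervals are contained in their window, and 10% of records are duplicated
(same trait and window, different PVE) to exercise curation.

**Expression.** Genes (default 7,750 ≈ 3.1 per window, the reported gene
density) carry one latent module factor each (75 modules):
`x_gs = w_g·ME_ms + sqrt(1 − w_g²)·ε_gs`, shifted by a per-gene baseline
and exponentiated to an FPKM-like scale so that log2(x+1) preprocessing
recovers the latent scale. Base loadings are Uniform(0.55, 0.75);
`hub_effect` = 0.026 is added to genes in parallel windows. That value is
calibrated so the *realized* gene-level kTotal ratio between parallel and
other genes is 1.2 (the reported 1.2-fold connectivity elevation): the
naive closed-form solution of E[(w+δ)^β]/E[w^β] = 1.2 under-delivers
because finite-sample noise in each gene's factor alignment attenuates the
elevation. With β = 6 the dominant source of kTotal dispersion is exactly
that alignment noise (≈ β/√S relative scale at S samples), which is why
`n_samples` defaults to 100 — the replication level at which the network
statistics stabilize — and why the loading *width* barely affects the
contrast's precision.

**Tracks.** Map markers every 250 kb with per-interval rates
Gamma(shape 4, mean 4 cM/Mbp), cumulative cM hence monotone; dS per window
Normal(0.92, 0.05) truncated to (0, 2) by redraw; track gene counts
Poisson(3.1) per window. These match the reported nonparallel-class track
means.

**Seeding.** One master seed; each component (truth, genotypes, QTL,
expression, tracks) derives its stream from a fixed spawn-key offset, so
components regenerate independently and fixture files are byte-identical
for a fixed (seed, config).

## Numerical choices and degenerate inputs

- Monomorphic sites give exactly zero variance components (no tolerance
  needed); near-zero denominators cannot arise otherwise.
- Sites with a single diploid in each population leave the estimator
  undefined (n̄ = 1); they are flagged non-variable.
- Integer soft powers are computed by exponentiation-by-squaring on the
  |correlation| matrix; kTotal matches a brute-force double loop to 1e-10.
- Exhaustive permutation comparisons use a 1e-12 slack when counting
  |null| ≥ |observed| to absorb summation-order float differences.
- All-equal F_ST values yield zero outliers (nothing strictly exceeds the
  quantile); all-equal connectivity leaves the scale-free fit undefined.
- Truncated-normal dS is drawn by redraw rather than inverse-CDF; the
  truncation mass is negligible at the default parameters.

## Problem sizes used in the test suite

Unit tests run on toy grids (tens of windows). The calibration check uses
500 replicates of a 300-window null at 2,000 permutation iterations. The
survey-scale recovery check runs 100 effect replicates and 50 null
replicates of the full default design with 500 permutation iterations per
contrast — enough resolution to score p < .05 while keeping a full-suite
run in the minutes range. The reproduction script
(`scripts/acceptance.py`) runs one full default-scale analysis at the
standard 10,000 iterations.

## Known limitations

- No linkage disequilibrium or coalescent structure: window F_ST values
  are independent across windows given the truth classes, so the
  permutation null is exactly correct on synthetic data; on real data,
  autocorrelation along the genome makes window labels non-exchangeable
  and the permutation p-values anti-conservative.
- Complete data everywhere: real reduced-representation data has strong
  window missingness, which lowers chance outlier sharing; the generator's
  complete-data design is the harder case for class purity.
- The QTL curation implemented is the main published rule set
  (midpoint placement, per-window trait deduplication, two-stage PVE);
  finer curation conventions (e.g., bilateral trait variants) differ
  between databases and are not modeled.
- The "Euclidean distance option" of the reference network implementation
  has no effect on kTotal as defined and is not emulated.
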