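# Methods

This note documents the models behind `pstfst`, the conventions the
package commits to where the literature leaves a choice, and what the
synthetic-data generator does and does not emulate.

## Dominant-marker allele frequencies

A dominant marker (an AFLP band) is scored 1 when at least one dominant
allele is present, so the genotypes AA and Aa are indistinguishable and
only the recessive homozygote aa (band absent) is directly observable.
Under Hardy–Weinberg proportions within populations, the probability of
band absence is q², where q is the frequency of the band-absent allele.
Two estimators of q from a count x of band-absent individuals out of n
scored are provided:

* **sqrt** (default): `q̂ = √(x/n)`, the method-of-moments estimator.
* **bayesian**: the posterior mean of q under the likelihood
  `x ~ Binomial(n, q²)` and a Beta(a, b) prior whose shape is fitted by
  the method of moments to the across-locus distribution of pooled
  band-absence fractions (a non-uniform prior). The posterior mean is
  computed by fixed-order Gauss–Legendre quadrature (order 256) on
  [0, 1], in log space; it is deterministic and is validated against a
  10⁶-point Riemann-sum oracle. If the across-locus moments are
  incompatible with any Beta distribution (zero or excess variance) the
  fit is flagged degenerate and a flat Beta(1, 1) is substituted with a
  warning.

The default is `sqrt` because of a measured property that matters for
the divergence statistics built on top: on island-model simulations at
the package's reference design (11 populations × 15 individuals × 500
loci), the sqrt plug-in recovers the generating differentiation
parameter F within ±0.05 for F ∈ {0.05, 0.15, 0.33}, whereas plugging in
the Bayesian posterior means deflates F_ST by roughly a factor of two at
these sample sizes: shrinkage moves near-fixed frequencies toward the
interior, inflating within-population heterozygosity and compressing
among-population variance. The Bayesian estimator remains available for
per-locus frequency estimates, where its stabilisation of boundary
counts is the point.

Missing marker cells are excluded per locus and population (complete
case); nothing is imputed.

## Gene-diversity partition and F_ST

Per locus and population, expected heterozygosity is `2q̂(1−q̂)·n/(n−1)`
(the small-sample correction matters at the 11–22 individuals per
population this package targets; cells with n < 2 are excluded). Hj is a
population's mean over loci; **Hw** is the unweighted mean of Hj over
populations; per-locus total diversity is `2q̄(1−q̄)` with q̄ the
unweighted mean allele frequency across populations; **HT** is its mean
over loci; **Hb = HT − Hw**, floored at zero with a warning (estimator
noise can produce small negatives); **F_ST = Hb/HT**. Unweighted means
are used throughout — the convention of the AFLP packages this mirrors
is not published to the bit, so the identity HT = Hw + Hb and simulation
recovery stand in for bit-matching.

Significance is by permutation of individuals among populations with
population sizes preserved, recomputing the full pipeline each time;
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), so p = 0 is never reported.
The Beta prior (Bayesian method) is fitted once: the pooled band-absence
fractions are invariant under label permutation.

**Pairwise F_ST** applies the same partition to each pair of
populations. Note a structural property of the two-population Nei
partition: the among-component of a pair captures only half of the
between-population variance, so under the island model
E[pairwise F_ST] ≈ F/(2−F) — at F = 0.33 pairs centre near 0.20, below
the global value. Pairwise values from this package are internally
consistent but not numerically comparable to corrected estimators used
by some legacy software.

## Outlier scan

Per-locus F_ST is the partition applied locus by locus. The neutral null
is simulated from the Balding–Nichols island model at the observed
global F_ST and the observed sample sizes: ancestral band-absent
frequency q0 ~ Uniform(0.1, 0.9) (the range avoids uninformative
quasi-fixed loci), per-population frequency
q ~ Beta(q0(1−F)/F, (1−q0)(1−F)/F), binomial sampling of band-absence
counts, and the same frequency estimator as applied to the data. A locus
is flagged when its F_ST strictly exceeds the empirical 99.5% quantile
of ≥1000 simulated neutral loci; downstream analyses use the unflagged
subset. This is a frequentist screening surrogate filling the role of
Bayesian posterior-odds outlier detection: deterministic under a seed,
desk-scale, and with measured type-I control (flag fraction ≈ 0.25% at
the 99.5% threshold on fully neutral data).

## P_ST

For each trait a one-way decomposition gives
`MSB = Σ nᵢ(x̄ᵢ−x̄)²/(k−1)` (grand mean weighted by nᵢ) and
`MSW = Σ (nᵢ−1)sᵢ²/(N−k)`, computable identically from individual-level
data or from per-population (mean, SD, N) summaries. Then

    P_ST = (c/h² · σ_B²) / (c/h² · σ_B² + 2 σ_W²),   σ_B² ≡ MSB, σ_W² ≡ MSW.

The mean squares are used directly — not the moment estimator
(MSB−MSW)/n₀ and not REML. This convention is deliberate: applied to the
packaged per-population summary table at c/h² = 0.5 it reproduces the
published per-trait P_ST values (stipular spine length to three
decimals; fruit width/length within the rounding the summaries carry),
while the moment-estimator convention lands far away (≈0.51 for fruit
width). c/h² — the proportion of between-population variance that is
additive over the within-population narrow-sense heritability — is an
assumed sensitivity parameter, never estimated; c and h² never appear
separately.

**Confidence intervals** are 95% percentile bootstrap intervals from
9999 replicates by default: stratified resampling of individuals within
populations (preserving nᵢ) for individual-level data, or a parametric
normal bootstrap drawing nᵢ values from N(x̄ᵢ, sᵢ²) per population when
only summaries exist (an explicit approximation of the unavailable raw
resampling). Populations with nᵢ < 2 are excluded from resampling. A
known limitation, measured and accepted: both schemes condition on the
realised population effects, so the χ²(k−1) between-replicate variation
of MSB is outside the interval, and coverage of a generator-level target
falls below nominal when σ_B is large (≈73% at an expected P_ST of 0.8
with 11 populations of 15). The intervals are comparative tools against
F_ST, not calibrated frequentist intervals for a superpopulation
parameter.

**Critical c/h²** is the smallest ratio at which the lower CI bound
reaches F_ST, found by bisection on (0, 2] to 10⁻³ (or on an explicit
grid). One bootstrap resample set of (MSB, MSW) pairs is drawn once and
re-evaluated at every c, which makes ci_low(c) nondecreasing in c and
the bisection exact; +∞ is returned when the bound is never reached.
Classification: critical ≤ 0.5 → `diversifying_strong`;
0.5 < critical < 1 → `diversifying_weak`; otherwise the CI at c/h² = 1
decides `indistinguishable` (straddles F_ST) vs `uniform_stabilising`
(entirely below). The default sensitivity grid for curves is 0.05–2.0 in
steps of 0.05.

## Nonparametric trait ANOVA

Kruskal–Wallis H with midranks and the tie correction
1 − Σ(t³−t)/(N³−N), p from χ²(k−1) (group sizes in the target designs
are ≥4, so the asymptotic approximation is used; exact enumeration is
out of scope). Dunn's post hoc z uses the joint-rank variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)); adjustment across the k(k−1)/2
comparisons is `none` by default (no correction is imposed that the
emulated analyses did not report), with Bonferroni and Holm available.

## Distance matrices and Mantel tests

Geographic distances are haversine great-circle kilometres (Earth radius
6371.0088 km) from signed decimal degrees (south/west negative; a DMS
parser handles `D°M′S″` with glyph variants). Replacing map-tool ruler
measurements with great circles changes distances by ≲0.3% at
intra-continental scales — immaterial to a rank-robust matrix
correlation. Environmental and trait distances are Euclidean over
(optionally z-scored) site variables.

The Mantel statistic is the Pearson correlation of strict lower
triangles; the null permutes rows/columns of the second matrix
simultaneously; p-values are one-sided (positive association) with the
+1 correction. The partial Mantel r conditions on a third matrix via the
first-order partial-correlation formula and permutes the second matrix
under the null; conditioning on a constant matrix reduces exactly to the
simple test. Which matrix is conditioned on is an explicit argument —
published "A vs B vs C" tables are ambiguous on this point, so both
readings can be run. Measured type-I error at α = 0.05 is within
[0.03, 0.07].

## Redundancy analysis

Columns of Y (sites × traits) and X (sites × environmental variables)
are centred and, by default, scaled to unit variance. Ŷ is the least-
squares projection of Y onto X's column space; R² = ‖Ŷ‖²/‖Y‖²; canonical
axes come from the SVD of Ŷ with signs canonicalised (first non-zero
response loading positive). Adjusted R² is Ezekiel's
1 − (1−R²)(n−1)/(n−m−1) (may be negative). Permutation tests use
pseudo-F: rows of Y permuted for the full model and axes; Freedman–Lane
residual permutation under the reduced model for individual terms.

Forward selection admits, at each step, the candidate adding the most R²
if (a) the step's permutation p ≤ α where the null statistic is the
**maximum** added-variance pseudo-F over all remaining candidates —
testing the argmax candidate against its own marginal null inflates
admissions badly (30–60% spurious additions after a true variable in
planted-signal trials) — and (b) from the second step onward the
cumulative adjusted R² stays at or below the full model's adjusted R²
(the overfitting cap). The cap exempts the first step because one strong
predictor can legitimately beat the full model on the adjusted scale;
applied verbatim, the cap can otherwise return an empty selection in
exactly the cases where selection is easiest. Perfectly collinear
candidates add no R² and are never admitted twice.

## Synthetic data

The generator emulates the study design the pipeline targets: 11
populations (default per-site sample sizes 16, 22, 14, 14, 14, 12, 12,
14, 17, 11, 12 — between 11 and 22 individuals, 158 in total), 225
dominant loci at global F_ST 0.33, seven quantitative traits with strong
between-population differentiation, and sites in a southern-hemisphere
bounding box (34.7–24.6°S, 66–56.5°W) with precipitation rising eastward
and temperature rising toward the equator; five further climate
covariates (min/max temperature, vapour pressure, solar radiation, wind
speed) are noisy linear mixtures of the two gradients.

Markers follow Balding–Nichols (exact E[F_ST] = F at the frequency
level) with HWE within populations. Traits are population effects
N(0, σ_B) plus individual noise N(0, σ_W), with σ_B calibrated through
the expected mean squares so the MS-convention estimator is centred on
the target at c/h² = 1: σ_B² solves target = E[MSB]/(E[MSB] + 2σ_W²)
with E[MSB] = n̄σ_B² + σ_W². Because E[MSB] ≥ σ_W², this calibration has
a floor: targets below 1/3 are unattainable and σ_B is clamped to zero
with a warning — a target of 0.2 therefore yields data whose estimated
P_ST centres near 1/3, not 0.2. Traits are generated independently
(no within-population trait covariance), without G×E, and loci without
linkage disequilibrium or mutation/migration history; passing tests
demonstrate estimator behaviour under this idealised model, not under
real field data with plasticity, measurement error, or shared ancestry
structure. Optionally a trait's population means can be tied to a
climate variable (coefficient × z-scored site value), which is what
makes trait–environment Mantel and RDA signals recoverable end to end.

All generators are bit-reproducible under a seed; every stochastic
routine in the package takes an explicit seed and derives child seeds
below 2³¹.

## Problem sizes used in the shipped checks

Simulation-based checks run at 11 × 15 × 500 loci (F_ST recovery, 10
seeds per level), 100 seeds × 999 bootstrap replicates (P_ST recovery
and coverage), 500–1000 replicates × 199 permutations (type-I error for
Mantel and RDA), and 50 end-to-end pipeline runs with 2000-locus
simulated nulls. These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping the whole suite in the tens of
seconds.
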