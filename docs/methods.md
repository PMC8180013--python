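# Methods

## Scoring

Raw readings are milli-OD (mOD) at 600 nm, one row per well in a long CSV
(`genotype,carbon,temperature_c,replicate,mOD,is_blank`). For each assay
environment (carbon × temperature) the blank is the mean of that
environment's blank wells; blank subtraction is clamped at zero
(`max(raw − blank, 0)`) so net yields stay in the score's domain. How
negative nets should be handled is genuinely open for real reader data, so
the clamp can be disabled (`clamp_negative=False`) for sensitivity checks.
Technical replicates are averaged **on net mOD** and the score

s = log10((mOD_MA + 1) / (mOD_anc + 1))

is formed once per genotype × environment from the two replicate means. The
alternative convention — score each replicate against the ancestor mean,
then average the scores — is exposed as `score_then_average`; the two
coincide when replicates are equal and differ only at second order
otherwise.

Carbon bookkeeping: all substrates are supplied at 0.4 g/L, which the
`carbon_molarity` helper converts to mM of carbon atoms using conventional
atomic weights (C 12.011, H 1.008, O 15.999): 13.3 mM C for the hexoses,
13.0 for glycerol, 14.0 for the disaccharides, displayed at 3 significant
figures and carried unrounded in computation.

## Variance partitioning and the R/I decomposition

At each temperature the G×E cell-mean matrix is partitioned by method of
moments: σ²G is the sample variance (denominator G−1) of row means, σ²E the
sample variance (E−1) of column means, and σ²GE = SS_int/((G−1)(E−1)) from
the interaction residuals x_ge − rowmean_g − colmean_e + grandmean. The
interaction decomposes over **ordered** genotype pairs (G(G−1) terms) into
responsiveness R = Σ(σ_Ei−σ_Ej)²/(2G(G−1)) and inconsistency
I = Σσ_Eiσ_Ej(1−ρ_EiEj)/(G(G−1)), with σ_Ei the E−1 sample SD of genotype
i's profile and ρ the Pearson correlation.

These denominator conventions are the unique sample-variance choices under
which R + I = σ²GE holds *exactly* (expand both sides in the row-centered
matrix: R + I = [Σᵢσᵢ² − ΣᵢⱼcovᵢⱼG⁻¹·…] collapses to SS_int/((G−1)(E−1))).
`partition` verifies the identity to 1e-9 relative on every call and raises
if it fails, since a violation can only mean an implementation or
conditioning bug. Summing unordered pairs with the same denominators would
halve R and I and break the identity.

Numerical/degenerate choices:

* A genotype with zero environmental variance has undefined correlations;
  these are stored as flagged nulls (NaN) with a warning and contribute 0 to
  I (their SD product is already 0). The identity still holds.
* "Total" variance is defined as σ²G + σ²E + σ²GE, so the partition is
  additive by construction rather than the raw variance of all cells.
* Replicate error is not subtracted from the interaction term: the analysis
  operates on replicate means, and the components estimated are those of the
  cell-mean table.
* Correlations are clipped to [−1, 1] against floating-point overshoot.

`pairwise_oracle` recomputes R, I and σ²GE by explicit double loops (with
scipy's Pearson correlation as an independent path) and exists purely as a
test oracle.

## Classification

Loss criteria are fractions f ∈ {0.99, 0.95, 0.90} with cutoffs log10(f);
the comparison is strictly `<`, so a score exactly at the cutoff is not a
loss (ties have measure zero on real data but matter in tests). Categories:
below on all E substrates → resource-independent deleterious; on ≥ 1 but
< E → resource-dependent deleterious; on none → non-deleterious. Proportions
use all G genotypes as denominator at every temperature × threshold, and
the three categories always sum to G.

## Trend models

Component-vs-temperature fits are OLS on [1, T, T²] with temperature
centered at its mean before squaring (conditioning only; coefficients are
back-transformed to the raw Celsius scale, so fitted values and tests are
centering-invariant). Per-term marginal (drop-one, Type II) F tests are
reported for the full model; model simplification removes the quadratic
term first if p ≥ α (default 0.05), refits, then tests the linear term
against the intercept-only model. A significant quadratic keeps the linear
term (marginality). Interpolating fits (zero residual) are handled by
treating an exactly-zero extra sum of squares as F = 0 and anything else as
indispensable.

Proportion trends are binomial GLMs with logit link fitted by IRLS
(statsmodels GLM; tolerance 1e-10, ≤ 100 iterations); the trend statistic
is the likelihood-ratio χ² (1 df) of the linear model against the
intercept-only model, and a quadratic term is added and LR-tested the same
way, retained only if significant. All-zero or all-total counts are
complete separation: the fit is refused, the slope reported as sign-only
(0) with a warning and a `separation` flag rather than a divergent
estimate.

## The synthetic-data generator

`simulate` emulates the default study design — 10 MA genotypes + ancestor ×
6 carbon substrates × 10 temperatures (23–41 °C in 2 °C steps) × 3
technical replicates, with one blank well per assay environment (2,040 rows
per dataset). Effects live on the score scale and are inverted exactly
through the score formula to mOD, so the noiseless score surface and its
variance components are exact ground truth:

s_gc(T) = −δ_g·λ(T) + η_g·x_c·ψ(T) + ε_gc·ω(T)

* δ_g ~ |N(0, σ_δ)| with σ_δ = 0.1: deleterious magnitudes; the median MA
  line loses ~15% of ancestral yield, within the range seen in MA growth
  assays after a few hundred generations. λ(T) = d0 + d2(T−T_mid)² with
  d0 = 1, d2 = 0.001, T_mid = 31 °C makes losses mildest at intermediate
  temperatures, so the mean relative score is negative everywhere with its
  maximum at T_mid.
* η_g ~ N(0, σ_η), σ_η = 0.06, against a fixed centered unit-variance
  carbon axis x_c (evenly spaced; deterministic so "responsiveness" means
  the same thing across seeds). The ramp ψ(T) = 0.2 + 0.05(T−23) makes
  genotypes' environmental SDs fan out with temperature: responsiveness
  grows ∝ ψ².
* ε_gc ~ N(0,1) idiosyncratic genotype-by-carbon effects, drawn once and
  scaled by ω(T) = 0.005 + 0.001(T−23): profile decorrelation — hence
  inconsistency — grows with temperature.

Choosing d2 small relative to the ramps is structural, not cosmetic: a
genotype's classification trajectory across temperature is one-directional
(independent → dependent → non-deleterious transitions never reverse)
precisely when λ's per-step relative growth stays below ψ's and ω's at
every temperature, which for these ramps requires d2 ≲ 0.003. With
d2 = 0.001 the seed-averaged proportion of resource-dependent genotypes is
monotone non-decreasing with comfortable margin, while the mean-score
maximum at T_mid is preserved.

The measurement layer: ancestral net yield follows a broad Gaussian thermal
performance curve per carbon (peaks 800–1500 mOD at 35.5–38 °C, breadths
11–13 °C — yields stay ≥ ~250 mOD at every assay temperature, as for a
mesophile assayed inside its thermal niche); MA net means are
(A_c(T)+1)·10^s − 1; replicates add N(0, σ_rep = 5 mOD) truncated at zero
(a warning reports the clamp rate); each environment's blank offset
(N(40, 3) mOD, drawn once) is added to every culture well and reported
exactly in the blank row. Omitting reader noise on the blank well keeps
ground truth exact by construction; for scores this noise is second order
anyway, since a blank error shifts the MA and ancestor wells of an
environment alike. One generator stream seeded by a single integer drives
effects and noise, so a (config, seed) pair reproduces a dataset byte for
byte.

What the generator does **not** emulate: incubator effects (confounded with
temperature in a one-incubator-per-temperature design), growth kinetics
(endpoint yield only), any mutational process (no genomes or substitution
counts), and systematically correlated sensitivities. On that last point: η
is zero-centered, so opposite-sign sensitivity pairs have ρ = −1 and push
interaction variance into inconsistency, capping the responsiveness share
of σ²GE near 36% even with ω = 0 (the defaults give ~25%). Real MA panels
can show responsiveness-dominated interaction instead; passing tests
therefore demonstrate correct *recovery* of R and I and their temperature
trends, not any particular R:I ratio in nature.

## Problem sizes and tolerances in the test suite

Multi-seed checks use 50 replicate datasets (a 50-seed batch runs in a few
seconds), recovery is asserted at 10% relative with a 1e-4 absolute floor
per component per temperature on ≥ 90% of seeds, the decomposition identity
at 1e-9 relative over 1,000 random matrices (2 ≤ G ≤ 12, 2 ≤ E ≤ 8), hand
fixtures at 1e-12, the noiseless parabola at 1e-8, and the binomial slope
within 5% of truth against a grid-refinement likelihood oracle at
1,000 trials per temperature.

## Known limitations

* Method-of-moments on cell means only; no REML/mixed-model variance
  components, and the mixed model for raw scores (incubator as random
  factor) is deliberately left to external tools — the pipeline emits the
  score table they need.
* The per-environment blank is an assumption; readers that share one blank
  per plate across carbons are handled by duplicating the blank row.
* Proportion trends treat genotype outcomes as independent binomial trials
  at each temperature; with 10 genotypes assayed repeatedly this is an
  approximation (the same genotypes appear at every temperature).
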