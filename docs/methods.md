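# Methods

## Model

Lifetime cancer mortality of breed *k* is modelled as a sum of
multi-stage terms over candidate driver-mutation counts *m*:

    p̄_k = A2·W_k·T_k² + A3·W_k·T_k³ + A4·W_k·T_k⁴ + A5·W_k·T_k⁵ + A6·W_k·T_k⁶

with every A_m > 0 and no intercept. The weight factor W_k stands in for
cell number; T_k is the breed's *size-predicted* lifespan from the
linear law T = a − b·W, never a registry value. Using the predicted
lifespan removes the feedback by which a breed's own cancer mortality
shortens its measured lifespan, which would otherwise contaminate the
regressor. The candidate range m ∈ {2..6} covers the biologically
plausible span of rate-limiting driver counts. Because the model is
linear in the A_m, every fit is an exact zero-intercept linear least
squares problem; an iterative nonlinear minimiser applied to the same
objective must converge to the same optimum (this equivalence is a
tested invariant).

## Lifespan law

The default law T = 13.3 − 0.08·W (years, kg) is the breed-number-
weighted pool of two published regressions (12.6 − 0.08·W over 81
breeds; 14.0 − 0.08·W over 77 breeds in 7 breed groups). Pooling
averages coefficients rather than refitting, because the inputs are
published fitted lines, not raw points. The printed one-decimal
intercept 13.3 is the default; the unrounded pooled value (13.2823…) is
available by pooling explicitly with `pool_regressions`. The law's
domain ends where T reaches zero (a/b ≈ 166 kg); predictions outside it
raise rather than extrapolate.

## Stepwise selection

Selection starts from the lowest power {2}; at each step the next
higher unused power is added and the model refitted. After each fit,
terms with negative or non-significant coefficients (two-sided t-test,
α = 0.05 by default) are discarded and the walk continues from the
pruned set, scanning powers in ascending order; it stops when the newly
added higher power fails the screen while the retained set is fully
positive-significant. Every single-power model and every contiguous
pair is also fitted so the candidate report always contains the nine
standard rows. The best model is the minimum-AIC candidate whose
coefficients are all positive and significant; candidates within
|ΔAIC| < 2 of it (and themselves admissible) are reported as
equivalent. ΔAIC is quoted against the single-power {4} reference.

AIC is the Gaussian least-squares form n·ln(RSS/n) + 2(k+1), counting
the error variance as a parameter. Only ΔAIC between candidates on the
same data is consumed, which makes the additive constant irrelevant;
AICc is available as a switch for small panels. Negative coefficients
are handled by pruning after an unconstrained fit rather than by
nonnegativity-constrained optimisation, which keeps the candidate
table's bookkeeping (which rows had a negative or non-significant term)
inspectable. Predictions are clipped to [0, 1] only at reporting time,
never during fitting.

## Residual diagnostics

Excess cancer mortality is 100·(observed − predicted)/predicted.
Prediction bands are new-observation bands,
ŷ ± t_{q, n−k}·s·√(1 + x'(XᵀX)⁻¹x), because their purpose is to flag
individual breeds, not to bound the mean curve; one-tailed bands use
q = level, two-tailed q = 1 − (1 − level)/2. Band exceedance uses
strict inequalities.

The Grubbs test runs on raw residuals (observed − fitted), where
approximate normality is more defensible than on percent excess (a
config switch allows percent residuals for sensitivity analysis). The
two-sided critical value at level α is
((N−1)/√N)·√(t²/(N−2+t²)) with t = t_{α/(2N), N−2}; after each
significant detection the extreme point is removed and the test
repeated. Reported p-bounds invert the same relation with a Bonferroni
factor over the N candidate points, so a maximum significant at
α = 0.05 two-sided carries a one-sided bound below 0.025. On null
normal samples the iterated procedure's family false-positive rate
measures ≈ 4–5% at α = 0.05 (slightly conservative, as expected from
the Bonferroni construction).

## Associations

Correlations are Pearson r with two-sided t-based p-values on n−2
degrees of freedom, computed cell-by-cell with listwise deletion — each
(inbreeding measure, dataset, outcome) cell uses its own complete
pairs, so n varies across cells and no imputation is ever done. Clade
comparisons use one-way fixed-effects ANOVA on per-breed excess
percentages with Fisher's LSD pairwise tests on the pooled within-clade
mean square, without family-wise correction (LSD is the designated
a-posteriori procedure). Consistent above/below-expectation patterns
use the exact two-sided sign test, p = 2·min{P(X≤k), P(X≥k)} under
Binomial(n, ½), capped at 1. Inbreeding measures (SNP, WGS, ROH, HOM,
MHC) are consumed as published numbers; nothing here estimates them
from genotypes.

## Dataset assembly

Trauma exclusion renormalises the cause-of-death denominator,
p' = p/(1 − trauma fraction), matching the removal of accidental deaths
from a proportion rather than subtracting from the numerator. Consensus
weights reduce each source hierarchically (mean within sex, then
between sexes), then screen sources iteratively: a value is dropped
when it deviates from the mean of the remaining values by more than 3
standard errors of those values, re-testing after each removal, with
the reference (kennel-club-style) source never removable. Breed-form
merges (miniature/standard forms) follow a shipped, editable YAML
mapping whose nesting defines the hierarchical averaging order; a
partial breed→clade mapping ships the same way. Multi-dataset
normalisation applies, per dataset, the affine map
x → m* + (x − m_d)·(s*/s_d) to all mortalities, where (m_d, s_d) are
the dataset's mean/SD over the shared breeds and (m*, s*) the
across-dataset averages of those statistics; SD uses the sample (n−1)
definition. Whether the original normalisation matched SDs exactly per
table or only in aggregate is not decidable from the published
description; the per-table affine construction is the natural reading
and is idempotent, which the tests verify.

## Cross-species calibration

Two species at the same equilibrium lifetime cancer risk satisfy
C_h·(uk·T_h)^Mh = C_l·(uk·T_l)^Ml, giving the closed form
uk = [C·L^Mh·T_l^(Mh−Ml)]^(−1/(Mh−Ml)) with C the cell-number ratio and
L the lifespan ratio. With C = 2, L = 5, T_l = 10 y, Mh = 5, Ml = 4
this yields uk = 1.6×10⁻⁵ per year; at u = 10⁻⁶ per division,
k = 16 divisions/year, one stem-cell division per 23 days. The closed
form is cross-checked against a bracketing root-finder on the
log-equation over random parameter draws.

## Synthetic data

The generator emulates the structure the analysis assumes, with
defaults at the combined-panel study conditions: 85 breeds; weights
log-uniform on 2–77 kg so small and giant breeds are equally
represented (the empirical weight distribution is deliberately not
reproduced); lifespan law a = 13.3, b = 0.08 with 1.2 y of breed-level
scatter; a single true power M = 4 with A4 = 7.84×10⁻⁷; and binomial
sampling of cancer deaths out of ~200 recorded deaths per breed, the
default noise model because mortality is a proportion of deaths
(a Gaussian option exists for band-coverage tests). Optional clade
multipliers (e.g. a terrier-like ×1.55), planted outlier breeds, a
trauma-fraction law, and a standard-normal inbreeding score that
shifts lifespan by −0.5 y per SD (and, by default, has no direct cancer
effect) complete the panel. The ground-truth sidecar records every
latent quantity, so each pipeline stage can be checked against values
the generator knows exactly.

Multi-dataset panels share a 36-breed core, give 16 breeds to each
dataset pair, and fill to sizes (81, 68, 119). Per-dataset affine
perturbations are centred across datasets (offsets sum to zero, scales
average one): registries are modelled as disagreeing with one another
around a common calibration rather than all drifting in one direction,
which is also the regime the shared-breed normalisation is designed to
undo. Per-breed dataset-specific measurement noise (sd 0.01) and
independent binomial redraws provide the decorrelation between
registries. Everything is driven by one `numpy` Generator seeded from
the config, so a seed fully determines the output.

What passing tests on these panels do show: the fitting, selection,
banding, outlier and association machinery is correct and calibrated
under the stated noise model. What they do not show: robustness to
features of real registry data the generator omits — non-random breed
ascertainment, heteroscedastic death counts spanning 28–4400,
cause-of-death misclassification, and correlated clade/size structure.

## Problem sizes and numerics

The repeated-simulation checks use 50 seeds for selection-rate
estimates, 1000 null samples (n = 50) for the Grubbs false-positive
rate, and 200 fresh panels for band coverage; these sizes give
binomial standard errors comfortably inside the asserted tolerances
while keeping the suite fast. Degenerate inputs fail loudly rather
than silently: zero shared-breed variance, rank-deficient designs,
weights beyond the lifespan domain, trauma fractions of 1, and
zero-variance Grubbs inputs all raise (or warn and return empty, where
the operation has a natural empty answer). Ties in stepwise pruning are
resolved by scanning powers in ascending order.

## Known limitations

- The intercept-free model makes percent excess undefined where the
  predicted mortality approaches zero (very small breeds); excess
  percentages for sub-2 kg weights should not be over-interpreted.
- Grubbs assumes approximate normality of residuals; with binomial
  noise and unequal death counts the residuals are only approximately
  homoscedastic.
- The clade ANOVA treats breeds as independent within clades, ignoring
  finer relatedness.
- Absolute AIC values depend on the Gaussian-likelihood variant chosen;
  only ΔAIC ordering is meaningful across implementations.
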