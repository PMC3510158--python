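# Methods

## The problem

Two fishing/survey gears sample the same population with different size
selectivities. Given per-fish fork lengths (mm) for each gear, we want to
test whether the two length-frequency distributions differ, and to
attribute any difference to location (overall position) and/or shape
(skewness, modality). Everything is nonparametric: length compositions are
routinely multimodal, so parametric location tests mislead.

## Kernel density estimation

For a sample x₁…xₙ the estimate is the fixed-bandwidth Gaussian KDE

    f̂(y) = (n h)⁻¹ Σᵢ φ((y − xᵢ)/h).

No boundary correction is applied: fork lengths of the species this
package targets sit hundreds of mm above zero, so kernel mass leaking past
the origin is negligible. Evaluation grids span [min − 4h, max + 4h]
(beyond 4 bandwidths a Gaussian kernel carries < 10⁻⁴ of its mass); with
≥ 501 points the trapezoidal integral of f̂ is 1 within 0.005, which the
tests assert.

**Mode.** The reported mode is the grid argmax on a 1-mm grid aligned to
whole millimetres, matching the measurement precision of field length
data; ties resolve to the smaller length so output is deterministic.
`local_maxima` additionally reports secondary peaks (those above 5% of the
global peak) for describing bimodal compositions.

## Bandwidth selection

`sheather_jones_bandwidth` implements the two-stage ("level 2") direct
plug-in rule for the Gaussian kernel:

1. robust scale σ̂ = min(sample SD, IQR/1.349); if the IQR is zero (heavy
   central ties) the SD alone is used;
2. normal-scale eighth functional ψ₈ = 105/(32√π σ̂⁹);
3. pilot g₁ = (−2K⁽⁶⁾(0)/(ψ₈ n))^{1/9}, then ψ̂₆ by the kernel-derivative
   double sum at g₁;
4. pilot g₂ = (−2K⁽⁴⁾(0)/(ψ̂₆ n))^{1/7}, then ψ̂₄ at g₂;
5. h = (R(K)/(ψ̂₄ n))^{1/5}, R(K) = 1/(2√π).

Every step is location-invariant and scale-equivariant, so h(a·x + b) =
a·h(x) exactly; the tests assert this to 1e−10. The double sums are
evaluated by default on a linearly binned grid of 401 cells (counts
autocorrelation × kernel derivative at the lag distances); the exact O(n²)
sums remain available (`binned=False`) and serve as the oracle — the two
agree to ≪ 0.5% at the sample sizes of interest (n ≤ ~2000). Our binned
path keeps all lags rather than truncating the kernel at (4 + derivative
order) bandwidths as some implementations do, which costs nothing at 401
cells and tracks the exact sums more closely (~10⁻⁴ relative).

For a two-sample comparison the common bandwidth is the geometric mean
√(h₁h₂), so the larger sample does not drag the smoothing toward its own
optimum.

Variable/adaptive bandwidths and cross-validation selectors are out of
scope: the comparison test needs one fixed, common smoothing, not the best
possible single-density estimate.

## Permutation test of density equality

Statistic: the integrated squared difference T = ∫(f̂₁ − f̂₂)² dy by
trapezoid over the shared grid, both KDEs at the common h. For two groups
an unweighted ISD is used; under permutation of group labels any
sample-size weighting is rank-equivalent, so it would not change p.

Null distribution: the pooled sample is reallocated without replacement
into groups of sizes n₁ and n₂; T* is recomputed with the *same* h on the
*same* grid (the null fixes the smoothing — re-selecting bandwidths per
permutation would confound mass reallocation with bandwidth noise).
p = (1 + #{T* ≥ T})/(1 + N): the add-one convention keeps p in (0, 1].

Implementation notes: the permutation loop precomputes the kernel of every
pooled observation on the grid once (an (n₁+n₂) × grid matrix), so each
permuted T* is one selection-matrix product; 10,000 permutations on
~1,000 fish take a few seconds. The pooled sample is sorted and the
permuted split uses the canonical sizes {min(n₁,n₂), rest}, which makes
the statistic, the p-value and the band exactly invariant under swapping
the two samples.

**Shape-only variant.** With `standardize_first=True` each sample is first
standardised by its own median and SD, y = (x − median)/SD (denominator:
sample SD, n−1). A pure location shift then yields identical standardised
samples, T = 0 and p = 1 exactly; what remains testable is shape.

**Reference band.** On the square-root-density scale the sampling standard
error of a KDE is approximately constant in y, so the band is built there
and squared back:

    a(y) = (√f̂₁ + √f̂₂)/2,  se = √(R(K)(1/n₁ + 1/n₂)/(4h)),
    band = [max(a − se/2, 0)², (a + se/2)²],  centre a².

Equal samples sit strictly inside the band; where an estimate escapes it,
that length region drives the difference. The band is a diagnostic, not a
simultaneous confidence region.

## Bootstrap Kolmogorov–Smirnov test

D = sup over the pooled observed values of |ECDF₁ − ECDF₂| with
right-continuous ECDFs, exact under ties. Because mm-rounded lengths are
tied en masse, the asymptotic null law of D is unreliable; the p-value is
instead Monte-Carlo: resample n₁+n₂ values *with replacement* from the
pool, split into pseudo-groups of the original sizes, recompute D*, and
report (1 + #{D* ≥ D})/(1 + n_boots). The with-replacement draw follows
the established bootstrap variant of this test and distinguishes it from
the permutation scheme above; in the tie-free large-sample limit the
bootstrap p agrees with the asymptotic formula (asserted within 0.03 on
average in the tests). ≥ is used when counting extreme D*; at the default
100,000 draws the choice of ≥ vs > is immaterial.

## Synthetic data generator

Truncated Gaussian mixtures, drawn by component choice + rejection
sampling of each Gaussian draw against the truncation bounds (exact, and
cheap because all preset bounds keep ≥ a few percent of each component's
mass; bounds excluding > 99.9% of a component's mass are rejected as
pathological). Truncation emulates gear-selectivity cutoffs at small
lengths and a physiological maximum at large ones. The generator
reproduces the analytic truncated-mixture mean and SD within 1% at 50,000
draws (tested).

The three species-like presets encode the published summary structure of
the gear-comparison study this toolkit generalises, at the study sample
sizes:

| scenario | gear 1 (Line) | gear 2 (stereo-BRUVS) | expected outcome |
|---|---|---|---|
| `crubescens_like` | mode 400, σ 80, n 170 | mode 331, σ 85, n 366 | location differs (~69 mm, ~17%), shape does not |
| `earmatus_like` | mode 276, σ 70, n 264 | mode 281, σ 69, n 198 | no difference |
| `pauratus_like` | mode 379, σ 85, n 431 | bimodal 0.66·N(382, 60) + 0.34·N(600, 55), n 557 | location and shape differ; secondary mode ≈ 600 |

Unimodal presets truncate symmetrically at mode ± 3σ so the truncated
mode stays at the component mean. The snapper-like mixture's weights and
σs were chosen once so that the 600-mm component forms a genuine second
mode (peak-to-valley ratio ≈ 1.9 in the true density) that a
Sheather–Jones KDE at n = 557 recovers reliably. Three calibration presets
(`null_pair`, `shift_only` with a 60-mm shift, `shape_only` with matched
median/SD but unimodal-vs-bimodal shape) exercise the test battery's
operating characteristics.

What the synthetic data do **not** emulate: mm rounding ties (presets are
continuous; tie handling is tested separately on rounded data), skewed
single-gear selectivity curves, year-to-year pooling structure, or
measurement error. Passing tests therefore demonstrate correct estimator
and test behaviour under realistic shapes and sizes, not agreement with
any particular field dataset.

## Numerical and design choices

* Default replicate counts are 100,000 for both tests (CLI-overridable);
  tests and the acceptance script use 10,000 (pattern checks) or ≤ 1,000
  (unit checks), sizes at which the Monte-Carlo error on p is well below
  the decision thresholds involved.
* p-values use the add-one convention throughout, so 0 is never reported.
* CSV I/O writes doubles with `%.17g` and parses with round-trip
  precision, so write→read reproduces lengths exactly.
* Per-species seeds in the CLI derive from a `SeedSequence` of (user seed,
  species index): reports are byte-identical across reruns and species are
  independent streams.
* Mode-recovery tolerance: with a plug-in-optimal bandwidth the ratio of
  the KDE-argmax standard error to h is asymptotically sample-size
  *independent* (≈ 0.5 for a normal-shaped peak), so mode-recovery checks
  use a ± 1.5·h (~3 SE) radius; ± 0.5·h would fail ~ a third of honest
  replicates at any n.
* Histogram bin widths in figures default to 50 mm (40 mm suits smaller
  species); minimum-legal-length lines are cosmetic and never filter data.

## Limitations

* Two groups only; k-group density comparisons are out of scope.
* The permutation test conditions on the observed common bandwidth; its p
  is exact under exchangeability but ignores bandwidth-selection noise.
* No boundary-corrected KDE: inappropriate for length data near zero.
* The reference band is pointwise, one SE, diagnostic only.
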