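# Methods

## The measurement model

A chronological-lifespan screen follows non-dividing yeast populations
through stationary phase. Viability of each well is read by propidium
iodide (PI) staining: PI is membrane-impermeant, so only dead cells stain,
and the cytometer's red-channel intensity distribution is a mixture of a
dim live component and a bright dead component. The analysis chain is

    events → gate → viability fraction → survival curve → AUC → class.

### Gating

The live/dead threshold is Otsu's criterion (maximum between-class
variance) on the pooled log10 intensities of a plate batch, computed on a
256-bin histogram. Pooling is deliberate: a fully dead well has a single
intensity population and cannot be gated on its own, but contributes
cleanly to a pooled bimodal histogram. A fixed threshold can be supplied
instead (`PIGater(threshold=value)`); per-sample estimation is not the
default. Events with non-positive intensity are rejected at parse time
(they are outside the log-transform domain and indicate corrupted input).
Samples with fewer than `min_events` (default 5,000, i.e. half the nominal
10,000 events per sample) fail QC and become missing timepoints; nothing
is imputed.

### Survival curves and the AUC statistic

The logarithmic-phase sample defines 100% viability, so survival is
S(t) = 100·f(t)/f(0) with day 0 the log sample. Normalized values above
100% (day-t fraction exceeding the day-0 fraction through counting noise)
are retained and flagged, not clamped — clamping would bias areas downward
asymmetrically. The longevity score is the trapezoidal area under S(t)
over the observed days (units %·days); a missing interior timepoint is
bridged by the trapezoid's implicit linear interpolation, and the area's
span always equals the observed span (no extrapolation to unobserved
days). On the standard grid {0, 2, 4, 6, 8} a curve pinned at 100%
integrates to 800 %·days; immediate death (100, 0, 0, 0, 0) gives 100.

Strains are excluded, with a logged reason, when an external growth flag
marks them as showing no growth/regrowth, when no viable day-0 sample
exists, or when all stationary-phase samples failed QC.

### Replicate averaging

Replicate curves are summarised by loess: at each grid point the nearest
`ceil(span·n)` pooled observations get tricube weights and a local
polynomial is fitted by weighted least squares. Defaults are span 0.75 and
degree 2 (both exposed). The fit is a linear smoother l(x)'y, so the
pointwise 95% band is fit ± 1.96·σ·‖l(x)‖ with σ² estimated from the
smoother residuals (df = n − tr L). Two numerical choices matter: when a
neighbourhood contains fewer distinct day values than degree+1 the local
degree is reduced to keep the fit identifiable (otherwise the pseudo-inverse
returns a minimum-norm solution that is not an interpolant), and with zero
residual variance the band has exactly zero width. On noiseless linear
data with degree 1 and span 1 the smoother reproduces the OLS line.

### Classification

The three control strains carried on every plate define the longevity
classes: wild type (average), a short-lived and a long-lived reference.
Each class's AUC sample is summarised by mean m, sd s (n−1 denominator)
and replicate count n. The class likelihood of a mutant area a is the
posterior-predictive density of a new observation from a normal population
with unknown mean and variance — a location-scale Student t with df = n−1,
location m and scale s·√(1+1/n). This is the generative reading of
"reallocating equal priors with a t-test": a p-value is not a likelihood,
but the t-test's distributional core is, and with equal class priors the
resulting decision boundaries sit exactly at the midpoints of adjacent
class means when sd and n are equal (a property the tests verify by
bisection). A plain-Gaussian likelihood mode exists for sensitivity
analysis. All densities are evaluated in log space and normalized with
log-sum-exp, so extreme areas cannot underflow; mutants with several
replicates are classified on their mean area; near-ties (posterior gap
< 1e−6) are flagged ambiguous and conservatively called average.

### Enrichment

Term over-representation in a hit list uses the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), with the background defaulting to the
set of strains actually analysed — the sampling frame of a
deletion-collection screen — rather than the whole genome. Reported rows
must pass all of: overlap k ≥ 3, p < 0.05, enrichment (k/n)/(K/N) ≥ 1.5.
BH q-values are reported but not filtered on. The test is one-sided
(over-representation only). GMT parsing keeps the description column and
deduplicates members; gene identifiers are upper-cased before any
intersection.

### Redox probe

For a ratiometric H2O2 probe with excitation maxima near 400 and 485 nm,
oxidation raises the 485-excitation signal, so R = F485/F400 increases
with the oxidized fraction. After per-channel, per-cycle subtraction of a
non-expressing background strain, the degree of oxidation is

    OxD = (R − R_red) / (F_corr·(R_ox − R) + (R − R_red)),

with R_red/R_ox the ratios of fully reduced (DTT) and fully oxidized
(H2O2) control wells, taken as medians over the last cycles (the
post-injection plateau, robust to the transient), and F_corr an instrument
correction factor defaulting to 1, where the formula reduces to linear
interpolation. OxD is exactly 0 at R_red and 1 at R_ox regardless of
F_corr, monotone in R, and invariant to any common gain on both channels.
Values outside [0, 1] are clamped and flagged. OxD0 is the mean OxD over
the pre-treatment cycles (default 4, ≈2 min each).

## The synthetic screen generator

No raw per-well cytometry data accompany published screens of this kind,
so validation runs on synthetic screens with known truth. The generator
emulates:

- **Decay law**: v(t) = exp(−(t/τ_r)^k), a two-parameter Weibull flexible
  enough to produce both the concave and convex control-curve shapes seen
  in real screens. Defaults: shape k = 2; time-scales τ = 2/4/8 days for
  the short/average/long archetypes, giving screen-grid areas of roughly
  177/352/594 %·days.
- **Noise placement**: plate and replicate effects are normal on log-τ
  (τ_r = τ·e^(ε_plate+ε_rep), sd 0.02 and 0.05 by default), so v stays in
  [0, 1] by construction. Under these defaults adjacent classes are about
  ten pooled SDs apart — an easily separable screen; narrower archetype
  trios are used in tests to probe the failure direction.
- **Events**: each well×timepoint draws its dead count from
  Binomial(10,000, 1−v) and intensities from a log-normal mixture
  (log10 means 2.0 live / 3.5 dead, sd 0.25 each) — synthetic conventions,
  since instrument distributions are not published; all exposed in
  `FluorModel`.
- **Layout**: every plate carries the three controls exactly once;
  duplicate strains on one plate are rejected.
- **Reproducibility**: one master seed; every (plate, well, timepoint)
  draws from its own `SeedSequence` sub-stream keyed by indices, so
  enlarging a design never changes existing wells.

What the generator does *not* emulate: spectral compensation, doublets,
autofluorescence drift, carry-over between timepoints, regrowth in
stationary phase, or non-Weibull mortality plateaus. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
analysis chain, not the biology of any particular screen.

## Problem sizes and defaults in the validation suite

The test suite exercises the full event-level pipeline at 4 plates ×
96 wells × 5 timepoints × 10,000 events (≈1.9×10⁷ events) and the
replicated-controls design at 31 plates (31 control replicates, 100
mutants per class) at the count level, where per-event intensities add
nothing to the statistics being checked. The acceptance script re-runs
both from a single seed.

## Known limitations

- The loess band is a pointwise (not simultaneous) interval and ignores
  within-replicate correlation across days.
- The AUC convention is the raw trapezoidal area over the observed span; a
  per-day mean is available when comparing strains with different spans,
  but spans are equal by design in a plated screen.
- The classifier assumes a location-scale family per class fitted from
  control replicates; a kernel-density likelihood would relax normality
  but is not implemented.
- Enrichment matches no particular web service's background handling or
  term-redundancy collapsing; results depend on the supplied GMT and
  background.
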