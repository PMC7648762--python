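# Methods

## The model

`ichthyospec` treats a deep-sea ichthyolith record — individual fossil fish
tooth lengths with ages, summarised as an ichthyolith accumulation rate
(IAR, ichthyoliths cm⁻² Myr⁻¹) — as the trophically aggregated imprint of a
size-structured pelagic food web, and asks which ecological driver best
explains its variation through time.

The forward model has three parts.

**Allometry.** Tooth length maps to body size through a power law
`S_body = a · S_tooth^b` with tooth length entering as the dimensionless ratio
length/1 µm and body size expressed in the grid's units (metres).  `a` and
`b` are *community-average effective* parameters calibrated from the record,
not a species-level allometry; they absorb the unknown unit conversion
between the tooth axis and the body-size axis, so their fitted values are
meaningful only within this model's conventions.

**Trophic transfer.**  The food web lives on `N` logarithmically spaced body
size bins spanning 10⁻⁷–10¹ m (default `N = 200`, which resolves a ~5 µm-wide
primary-production peak on the eight-decade grid).  Primary production is a
Gaussian over *arithmetic* size (its mean `P₁^µ` and spread `P₁^σ` are stated
in µm), normalised to a fixed total (10⁴ relative units Myr⁻¹).  Production
passes through five trophic levels.  The diet of a predator of size `s` is a
Gaussian over log₁₀ prey size centred on `log10(φ·s)` with spread `σ` (in
log₁₀ size): `φ` is the preferred prey fraction of predator size, `σ` the
diet's generalism.  Each transfer multiplies total production by the trophic
transfer efficiency `α`.

*Discretisation.*  Diet proportions are normalised across prey within each
predator row (every diet sums to one).  Propagation, however, uses the
complementary prey-partitioned *flow* matrix — each prey bin's production is
split across its predators in proportion to their diet weight for that prey —
which is column-stochastic by construction.  This makes `α` the sole control
of between-level transfer: level totals satisfy
`Σᵢ P_{i,l} = α^{l-1} Σᵢ P_{i,1}` exactly on any grid, including near grid
boundaries where a row-normalised kernel would leak mass.  The kernel and its
normalisations are evaluated in log space (`logsumexp`/softmax), so even
near-degenerate kernels (`σ → 0`, or prey far from all predators) never
underflow to all-zero rows or columns.

**Tooth prediction.**  Production of the top trophic level (level 5 by
default) is mapped onto a tooth-length axis (106–2000 µm, 64 log bins by
default; 106 µm is the picking threshold of the target record) through the
inverse allometry and mass-conserving linear rebinning in log length.  The
choice of a single level is deliberate: with one level, changes in `α` or in
total primary production rescale the predicted density *exactly* without
moving its shape, which is the qualitative signature that separates
energy-flow drivers from predator–prey (shape) drivers.  Summing several
levels (configurable: levels 3–5 or 4–5) mixes different powers of `α` into
the aggregate and breaks that exact invariance; levels 1–2 (phytoplankton and
primary consumers) are toothless in any configuration.  A corollary worth
stating: with a single level, `α` and a total-production multiplier are
observationally equivalent (both are pure scale controls), so their
time-varying experiments produce essentially tied RMSE reductions and are
distinguished by the *size* of the per-Myr variation each needs, not by fit
quality.

## Data preparation

Measurements below 106 µm are dropped (logged).  Ages come from piecewise
linear interpolation of the age model's control points.  IAR is
`count / (area · duration)` per sample.  Samples are grouped into 1-Myr bins
(half-open `[edge, edge+width)`, oldest edge closed) over the 62–46 Ma study
window; the within-bin percent SD of sample IARs is the record's noise
summary.  Each bin's tooth lengths are smoothed with a Gaussian kernel on
log₁₀ length (Silverman's rule bandwidth per bin, recorded in the output; a
fixed 0.05 log₁₀ fallback for single-tooth bins, where the density is the
kernel itself) and rescaled so the density's integral equals the bin's
*relative* IAR — its mean IAR divided by the record mean — matching the
model convention that the reference state carries about one relative unit of
production per Myr.  The density axis starts at the 106 µm threshold, so the
sub-threshold tail is truncated consistently in both data and model.

## Calibration and the time-varying experiments

The misfit is the pooled sum of squared density residuals over all time bins
and size bins.  The static reference fit minimises it over
`θ = {a, b, α, σ, φ, P₁^µ, P₁^σ}` with Nelder–Mead from 20 Latin-hypercube
starts inside generous bounds (`α ∈ [0.01, 0.5]`, `φ ∈ [0.001, 0.5]`,
`σ ∈ [0.01, 2]`, `b ∈ [0.3, 2]`, `P₁^µ ∈ [1, 500]` µm,
`P₁^σ ∈ [0.5, 100]` µm; `a`, `P₁^µ`, `P₁^σ` are optimised in log₁₀), an
L-BFGS-B polish of the best candidates, and a keep-best guard so the result
never ends above its initialisation.  `θ` components trade off (the
allometric pair against `P₁^µ` in particular), so individual fitted
parameters are reference values rather than identified ecological constants;
recovery tests therefore assert the predicted density and trajectory shapes,
not all seven parameters.

Each time-varying experiment re-optimises *one* quantity — `α`, a total
primary-production multiplier (reference = 1), `φ`, or `σ` — independently in
each Myr bin, others held at their reference values (1-D bounded
minimisation in log₁₀ of the value, with the reference value kept when no
improvement is found).  Reported per experiment: per-bin RMSE (over size
bins), total RMSE (over all residuals), and the *reduction factor* =
reference total RMSE / experiment total RMSE, the model-ranking statistic.
When both RMSEs are exactly zero the factor is defined as 1.

The constrained-variation sensitivity bounds each bin's value within
±`max_pct` percent of the previous bin's fitted value, chaining forward in
time from the reference value (so `max_pct = 0` reproduces the reference fit
exactly; the alternative anchor — every bin within ±`max_pct` of the
reference — is a config flag).  A greedy forward pass is polished by a joint
L-BFGS-B over per-bin ratio variables, and the ladder
{5, 10, 20, 30, 40, 50, 100}% is swept warm-starting each level from the
previous solution (feasible by nesting), which together with the keep-best
guard makes total RMSE non-increasing in the constraint by construction.

The size–productivity-scaling variant re-runs the production experiment with
`P₁^µ` co-varying linearly with the production multiplier `m`:
`P₁^µ(m) = P₁^µ_ref · (1 + slope·(m − 1))`, default slope 1 (mean
phytoplankton size doubles when production doubles — the simplest
positive-linear choice; the mechanism, not the slope's exact value, is what
the variant probes).  `slope = 0` reduces exactly to the unscaled experiment;
negative slopes are rejected.

## Temperature regression

Sample IARs and the temperature record are averaged into common half-Myr
bins (bin-averaged on both axes, unweighted OLS; weighting by per-bin `n` is
exposed in config but off by default since the published figure plots plain
binned means).  `IAR ~ 1 + T + T²` is fitted by OLS; the quadratic term is
tested against the nested linear model with an F-test on (1, n−3) degrees of
freedom, and a pointwise 95% confidence band for the regression mean is
reported.

## The synthetic generator

The generator is the package's ground truth factory: it runs the same
forward model under known parameters and emulates the sampling chain of a
red-clay ichthyolith record.  Default conditions, chosen once:

| quantity | default | rationale |
|---|---|---|
| window / bins | 62–46 Ma, 1 Myr | the study interval and its binning |
| samples per bin | Poisson(4) | ~4 measurements per Myr bin in the target record |
| intra-sample noise | lognormal, 14% CV on counts | the record's ~14% within-bin SD |
| reference IAR | 100 ich cm⁻² Myr⁻¹ | centre of the record's 30–300 range |
| sample geometry | 4 cm², 0.25 Myr | gives ~100 teeth per reference sample |
| tooth axis | 106–2000 µm | picking threshold to beyond the largest teeth |
| θ* | α 0.1, φ 0.096, σ 0.236, P₁^µ 50.01 µm, P₁^σ 5.02 µm, a 6.41·10⁻⁵, b 1.6 | field-typical efficiency and size-ratio values; allometry placing top-level production at ~300 µm teeth |
| temperature link | P = 0.25 + 0.075·(T − 6)², noise 0.3 °C | bottom water ~7–12 °C over a ~10-fold production range |

Scenario trajectories are piecewise-linear in log₁₀ multiplier: the
`alpha-driven` preset holds a ~10-fold total-production excursion (low near
60 Ma, peak ~51–49 Ma) while never moving `α` by more than ~9% per Myr; the
`pp-driven` preset carries the same excursion on the production multiplier
(≤ ~40%/Myr); `phi-driven` dips the preferred prey fraction by 20%;
`pp-size-scaled` adds `P₁^µ` co-variation (slope 1); `constant` is the null.
Tooth counts are lognormal-perturbed expectations (the %SD is the stated
noise; no separate Poisson stage on counts), tooth lengths are inverse-CDF
draws from the discretised predicted density (uniform in log within a bin),
depths invert a linear 0.3 m Myr⁻¹ age model, and temperature inverts the
quadratic link on its increasing branch plus Gaussian noise.  Identical
spec + seed reproduces outputs byte for byte, and the truth JSON stores every
latent quantity.

What the generator does *not* emulate: taphonomic dissolution or transport,
morphotype/community change, age-model error, preservation gaps longer than
the Poisson sampling produces, or temperature-dependent physiology.  Passing
recovery tests therefore show the *inference machinery* is sound under the
model's own assumptions — not that those assumptions hold for any real
record.

## Numerical choices and degenerate inputs

Tolerances: level totals meet the `α^(l−1)` law to ~10⁻¹⁴ relative; diet rows
sum to 1 to 10⁻¹²; density integrals are rescaled to match their targets
exactly; the allometric round trip holds to 10⁻¹⁰ relative.  Forward-model
failures inside optimisation (e.g. an allometry that maps all production off
the tooth axis) score a large finite penalty rather than raising, and raise
with the offending parameters named when called directly.  Empty time bins
are flagged, logged and excluded from fitting; a production mean size outside
the grid warns and concentrates mass in the nearest bins.  Optimiser seeds
are explicit arguments everywhere; all pipeline randomness flows from one
master seed.

Problem sizes used by the shipped tests and the acceptance script — 200 size
bins, 64 tooth bins, 16 Myr bins, 6–20 optimiser starts, 10⁴ Monte-Carlo
replicates for the F-test calibration — are the package's default working
resolution; they resolve every feature the model produces while keeping a
full analysis in the minutes range on one core.

## Known limitations

* `α` and total primary production are observationally equivalent under the
  single-level tooth prediction; the record alone cannot separate them (the
  per-Myr variation each demands is the discriminating diagnostic).
* The seven static parameters are not individually identifiable; only the
  predicted density is.
* The kernel-smoothed density inherits the KDE's smoothing bias, absorbed at
  fitting time mostly by `σ̂`; bandwidths are recorded so sensitivity can be
  checked.
* Joint multi-parameter time-varying estimation is deliberately out of scope
  (under-determined on a trophically aggregated record), as is a power-law
  primary-production distribution and any absolute-biomass conversion.
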