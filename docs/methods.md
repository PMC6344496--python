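# Methods

## Model family

The package models lifespan-wide performance as the output of a growing,
senescing cell population.  The population grows as
`dN/dt = α(t) N(t)` with `α(t) = α₀ e^(−α_r t)`; the decaying rate
encodes replicative senescence and produces saturation at
`N_∞ = N₀ e^(α₀/α_r)`.  Average per-cell functionality declines as
`β(t) = β₀ (1 − e^(β_r(t−t_d)))`: near-constant in early life, dropping
to exactly zero at the time of death `t_d`.  Observable performance is
`P(t) = β(t) N(t)`, a five-parameter curve with three equivalent
algebraic forms (dimensional, asymptotic-scale, and reduced
dimensionless); the implementation keeps all three and tests their
agreement at 10⁻¹² relative tolerance.

Assumptions worth stating: cell types are aggregated into a single
averaged population (a general multi-type variant,
`multitype_performance`, integrates several independent populations and
collapses to the averaged model for one type); the age axis is anchored
at t₀ = 0 — the model's earlier "first cellular division" instant is not
representable and is not needed for fitting; growth and decline do not
interact except through the product form.

Moore's double exponential `a(1−e^(−bt)) + c(1−e^(dt))` is the empirical
reference model.  The Siler hazard is included because substituting an
age-dependent mature hazard `a₂(t) = a₁ + a₃ − 2a₁e^(−b₁t) − 2a₃e^(b₃t)`
into it reproduces Moore's form exactly — the structural bridge between
mortality modeling and performance modeling; this identity is enforced
by a property test at machine precision.

## Parameters and defaults

| parameter | meaning | units | typical range |
|---|---|---|---|
| `alpha0_star` = α₀t_d | initial growth pull | — | ~0.7 (mouse lemur) to ~1125 (thoroughbred) |
| `alphar_star` = α_r t_d | strength of growth saturation | — | ~0.4 to ~160 |
| `betar_star` = β_r t_d | steepness of terminal decline | — | ~3·10⁻⁴ (near-linear) to ~9 (abrupt) |
| `td` | time of death | years | species lifespan |
| `scale_inf` = β₀N_∞ | amplitude | performance units | data-dependent |

Small `betar_star` gives a quasi-linear decline to `t_d`; large values
preserve performance late and then collapse.  `τ = 1/α_r = t_d/α_r*` is
the e-folding time of growth-rate decay, comparable to organismal
growth-curve timescales.

## Peak age

The peak solves `d ln x/du = 0`:
`α₀* e^(−α_r* u) = β_r* e^(β_r*(u−1)) / (1 − e^(β_r*(u−1)))`.
The left side decreases monotonically, the right side increases to +∞ at
u = 1, so an interior maximum exists iff the growth pull dominates at
u = 0 (`α₀* > β_r*/(e^{β_r*} − 1)`) and is then unique.  It is located
by Brent root-finding on [10⁻¹², 1−10⁻¹²] (absolute tolerance well below
10⁻⁸ on u), with a dense-grid argmax fallback if bracketing fails
numerically; a monotone curve raises `DegeneratePeakError` carrying the
boundary argmax.  A 10⁶-point grid oracle validates the root-finder on
random shapes in the test suite.

Several published parameter rows do not reproduce their own published
peak ages (differences of 0.5–9 years for shotput, weightlifting,
marathon, greyhound and the three middle-distance running series — the
printed parameters are rounded to 2 decimals and the greyhound peak
appears to be in different units than its lifespan).  Fixtures carry a
computed `peak_consistent` flag instead of asserting those rows; batch
statistics over normalized peaks exclude the greyhound (unit-ambiguous)
and facial-recognition (lifespan fitted as 185 y, far beyond the
recorded human maximum of 122 y) series.

## Envelope extraction

"Top performance per age" is implemented as the per-bin maximum over
half-open bins `[k·w, (k+1)·w)` of the native age unit (1 year for
humans, 1 month for horses/greyhounds, 1 week for mice and mouse
lemurs), reported at bin centers converted to years (weeks ÷ 52.1775 =
365.25/7, months ÷ 12).  This is deliberately not a geometric convex
hull: an upper-concave-hull post-process is available
(`upper_concave_hull`) but off by default.  Sparse old-age bins are kept
as-is, never merged.  The envelope is idempotent and monotone under
record addition; both properties are tested.

## Fitting

Both models are fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, `trf`), which handles the positivity
bounds that the classic Levenberg–Marquardt update cannot.  IMAP1 is
fitted in the `(scale_inf, α₀*, α_r*, β_r*, t_d)` parameterization — all
shape parameters O(1)–O(10³) and the amplitude decoupled — with bounds
(10⁻⁶, 10⁴) on the shape parameters and `t_d ∈ (max age, 50·max age)`.
Default initialization: α₀* = 30, α_r* = 20, β_r* = 3 (the middle of the
human range), `t_d = 1.2·max(age)`, `scale_inf = 1.05·max(value)`; an
optional seeded multi-start (log-normal jitter) guards against local
minima and is used for the Moore fits, whose default initialization is
cruder.  Least squares is unweighted by default (per-bin counts can be
supplied as weights).  The covariance is `s² (JᵀJ)⁻¹` with
`s² = SS_res/(n−p)` from the Jacobian at the optimum, pseudo-inverted
and symmetrized.

Goodness of fit: `R² = 1 − SS_res/SS_tot`,
`adj R² = 1 − (1−R²)(n−1)/(n−p−1)` with p the fitted-parameter count,
`RMSE = √(SS_res/n)`, and
`AICc = n ln(SS_res/n) + 2p + 2p(p+1)/(n−p−1)` where p additionally
counts the error variance — the standard small-sample convention, used
consistently so ΔAICc comparisons are internally coherent (only the sign
of ΔAICc is treated as externally meaningful).  Curve similarity uses
classic dynamic time warping: absolute-difference local cost, symmetric
steps, no window.

## Credibility envelopes

Parameter vectors are drawn from the multivariate normal centered at the
estimates with the fitted covariance (default 100,000 draws; tests use
fewer).  Draws violating positivity are rejected and redrawn so the
returned count is exact; the rejection count is logged and a rejection
rate above 50% aborts, since the normal approximation is then
inconsistent with the parameter domain.  The band is the pointwise
min/max envelope containing *every* drawn curve — not a quantile band,
though `quantiles=(0.025, 0.975)` is available — with drawn curves
clamped at zero by default.  Diagnosing the late-age divergence of
Moore's model uses `clamp=False`, because clamping would eventually
collapse any band to zero once all drawn curves go negative; the
contrast of interest (IMAP1 closes at `t_d`, Moore widens) is a property
of the raw curves.

## Synthetic data

No raw data ship with the package; the generator stands in for the
original ranking-style sources.  `simulate_envelope` perturbs the model
envelope with multiplicative Gaussian noise (default 1% relative — of
the order of the scatter visible in elite-performance envelopes) —
suited to recovery experiments.  `simulate_population` draws `n_per_age`
individuals per bin at `curve·(1−|δ|)`, `δ ~ N(0, noise_scale)`: a
half-normal deficit below the top performer, so the sample maximum is
stochastically below the true envelope and converges to it as the cohort
grows (default 100 per age; the original cohorts range from a few
hundred records to ~58,000).  What the generator does *not* emulate:
secular trends across calendar years, sex structure, selection-line
genetics, heteroscedastic age coverage (masters' and juvenile bins are
sparser in real data), or measurement discreteness.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the model, not robustness to real-data artifacts.

Recovery under the study conditions (100 one-year bins, 1% envelope
noise, 50 seeded replicates of the sprint-speed truth) yields median
absolute relative errors of ~1–2% on the shape parameters and <1% on
`t_d`, comfortably inside the 10%/5% acceptance bands.

## Numerical choices

- `expm1` everywhere the decline factor appears, for accuracy near `t_d`.
- Exponents capped at 700 inside optimizer objectives only, to keep
  excursions finite; in-domain values are unaffected.
- Root-finding tolerance 10⁻¹⁰–10⁻¹² on u (all quantities O(1) after
  nondimensionalization); cross-form agreement asserted at 10⁻¹².
- Ties within an envelope bin do not affect the maximum; counts are kept
  for diagnostics.
- Degenerate inputs fail loudly: constant envelopes, under-determined
  series (fewer points than parameters + 1), unknown units, non-PSD
  covariances.

## Scope and limitations

Web scraping of the original data sources is out of scope, as are the
Heligman–Pollard mortality model, growth-curve fitting of external body
mass series, and mechanistic interpretation of β(t) (lipofuscin,
telomere attrition and similar candidates are narrative context, not
model structure).  The fitted `t_d` is an extrapolated curve parameter,
not a demographic estimate — the facial-recognition series shows how
sparse late-age data inflate it.  Problem sizes in the test suite (100
ages, 50 replicates, 10⁴ draws) were chosen as the smallest designs that
make the statistical properties unambiguous.
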