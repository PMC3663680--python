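# Methods

## Growth models

Tumour volume is modelled as either exponential,
`V(t) = V0·exp[SGR·(t−t0)]`, or Gompertzian,
`V(t) = V0·exp[(SGR0/λ)·(1−e^{−λ(t−t0)})]`, where SGR is the specific
growth rate `(1/V)dV/dt` (fraction/day), λ ≥ 0 the growth deceleration
constant (1/day), and the plateau volume is `V0·e^{SGR0/λ}`.  The
exponential model is the λ = 0 member of the same parameter family
(`GrowthParameters`), not a separate type: every routine handles both
branches, and the Gompertz exponent switches to its exponential limit
when `λ·|t−t0| < 1e-9` so the curve is numerically continuous in λ.
Negative SGR values are legal everywhere — non-growing lesions must not
be excluded, as dropping them biases the pooled regression — except in
the doubling-time conversion `DT = ln2/SGR`, which signals "no finite
doubling time" for SGR ≤ 0 distinctly from invalid input.

Internal units are days and cm³ throughout; %/day, months (1 month = 30
days, rounded half away from zero — the convention that reproduces the
reference doubling-time conversions) and calendar years appear only at
formatting boundaries.

## The time-eliminated estimator

Differentiating the Gompertz curve gives `SGR = SGR0 − λ·ln(V/V0)`: SGR
is linear in log volume and time drops out.  The pipeline therefore

1. computes the interval SGR `ln(V2/V1)/(t2−t1)` for each pair of
   *consecutive* measurements of each lesion (consecutive only — using
   all pairs would correlate the errors);
2. pairs each with the log geometric mean `(ln V1 + ln V2)/2`;
3. pools the records from all lesions and fits unweighted OLS of SGR on
   ln V.  Then `λ = −slope` and `SGR0 = intercept + slope·ln(V0)` with
   V0 = 10⁻⁹ cm³ (one cell) by default.  The slope's two-sided t-test
   (n−2 df) at α = 0.05 decides model selection: significantly negative →
   general Gompertz; otherwise heterogeneous exponential growth, with
   per-lesion rates summarised by the time-weighted mean of interval
   SGRs (equal to total log growth over total time).  A non-negative
   slope reports λ = 0 with a flag.
4. The fitted (SGR0, λ, V0 = one cell) define the general growth curve.
5. Each lesion is dated by the 1-D least-squares shift of that curve onto
   its measurements (log-volume residuals); the optimal shift is the
   lesion's formation time.  Under the heterogeneous-exponential branch
   lesions are instead dated by back-extrapolating their own exponential
   fit to one cell — there is no shared curve to shift.

Finally the sorted formation times, ranked 1..n, are fitted through the
origin, `ln(rank) = k·(t − t_first)`, giving the metastasis formation
rate k (reported per year, 365 days).  The through-origin form enforces
count = 1 at the first formation, matching the model's definition; r² is
computed uncentred, consistent with the absence of an intercept.  The
rate model is agnostic to whether a lesion seeded from the primary or
from another metastasis.

A useful exact identity (used by the tests): for equally spaced
measurements Δt apart on a noiseless Gompertz curve, interval SGR is
*exactly* linear in log geometric-mean volume with slope
`−λ·tanh(λΔt/2)/(λΔt/2)` and proportionally scaled intercept.  Plain OLS
therefore under-estimates λ and SGR0 by the factor
`tanh(h)/h ≈ 1 − (λΔt)²/12` — about 0.02% for λ = 2.3×10⁻⁴/day and
semiannual visits.  The package deliberately keeps plain OLS (the
method's defining operation) rather than inverting this factor.

## Direct curve fitting

Per-lesion exponential and Gompertz fits are always computed for
comparison.  Both minimise squared residuals in **log-volume** space:
measurement error is multiplicative, the exponential fit becomes exact
linear regression, and nesting is exact.  The Gompertz fit (≥ 3 points;
with two the deceleration is unidentifiable) optimises (SGR at first
measurement, λ ≥ 0, ln V at first measurement) with `scipy.optimize.
least_squares`, initialised from the exponential fit and from the
lesion's own SGR-vs-lnV slope when ≥ 3 intervals exist (else λ₀ = 10⁻⁴).
The exact λ = 0 solution is always evaluated as a candidate and kept if
it is no worse, so the nested-model property (Gompertz SSE ≤ exponential
SSE) holds by construction, to a 1e-10 tie tolerance.  r² = 1 − SSE/SST
in log space; a saturated fit (SST = 0 handled explicitly) reports
r² = 1.  Reported SGR0 for a direct fit is the rate the curve had at the
one-cell volume (the formation-time convention), obtained through the
linear SGR–lnV relation.  `compare_models` declares no winner when
|Δr²| is below an indifference margin (default 0.02) — the expected
situation on short windows, where formation times nonetheless diverge by
years.

## Shift fitting

`shift_fit` minimises `Σ[ln vᵢ − ln V_general(tᵢ − s)]²` over the scalar
shift s.  Each measurement alone yields a closed-form shift by inverting
the curve (`log1p` is used in the inversion to stay accurate as λ → 0);
the optimiser starts from their median, which for monotone data sits next
to the optimum of a unimodal objective, and polishes with 1-D
Levenberg–Marquardt to ~1e-8 days.  A single-point series returns the
closed-form inversion exactly (SSE = 0).  A measured volume at or beyond
the general curve's plateau is an error, not a silent clip.

## Synthetic cohorts

`simulate_patient` emulates the structure of the clinical data the
method targets: lesions appear over time and grow from one cell
(10⁻⁹ cm³), observed at sparse visits with multiplicative noise and a
visibility threshold.  Defaults encode the study conditions:

* shared-Gompertz truth SGR0 = 0.0079/day, λ = 0.00023/day at one cell —
  hepatic-cohort scale estimates; the heterogeneous-exponential scenarios
  in the tests use a pulmonary-like median 0.0024/day with lognormal
  dispersion σ = 0.35 (per-lesion rates spanning roughly 0.14–0.39 %/day);
* formation rate k = 0.5/yr, with lesion i+1 forming after a gap of mean
  `(ln(i+1)−ln i)/k` — deterministic exponential accumulation in
  expectation (an optional lognormal jitter randomises the gaps), chosen
  over a Poisson process because it matches the count model directly and
  keeps recovery tests sharp;
* eight semiannual visits starting at day 4500, i.e. lesions roughly a
  decade old at first imaging, clinically realistic ages for metastases
  followed by annual/semiannual imaging;
* detection threshold 0.1 cm³ (a documented, deliberately simple stand-in
  for "visible on imaging"); records exist only where the *true* volume
  is above threshold;
* measurement noise: volume × `exp(N(−σ²/2, σ))` with `σ = ln(1+CV)`,
  CV = 10% by default — mean-unbiased in volume, hence a known −σ²/2 mean
  in log space (tested at 10⁵ draws).

The same seed reproduces a cohort bit-for-bit; noise is drawn in a fixed
lesion × visit order independent of detection, so changing the threshold
does not reshuffle the stream.  What the simulator does **not** emulate:
treatment effects, immune control, lesion coalescence or spatial
constraints, imaging segmentation error structure beyond lognormal
volume noise, or any link between primary size and seeding rate.
Passing recovery tests on these cohorts shows the estimator is correct
under its own assumptions — not that real metastases follow a shared
Gompertz curve.

## Problem sizes and numerical choices

The validation suite uses desk-scale problems chosen to exercise the
estimator honestly: the 21-point worked example (exact cell-for-cell
reproduction of its reference table, rounding half away from zero);
noiseless end-to-end recovery on the 6-lesion default cohort (λ, SGR0
within 1%, formation times within 1 day — the residual error is the
finite-interval bias above, ≈0.7 days at these ages); 200 noisy
replicates at 20 lesions for the stochastic λ recovery (median within
20%); and 100 seeded heterogeneous cohorts of 7 lesions for
model-selection specificity (≥ 80% non-Gompertz calls; the observed rate
is higher because detection and volume–rate correlation push the pooled
slope positive under the heterogeneous truth).  OLS itself is delegated
to `scipy.stats.linregress` and verified against closed-form normal
equations to 1e-10.

Degenerate inputs are contracts, not crashes: duplicate measurement
times and non-positive volumes are rejected at parse time (lenient mode
drops them with a logged count); a single-measurement lesion yields no
interval records but can still be shift-dated; fewer than three pooled
records aborts the linearized stage with the reason recorded in the
report's `skip_reasons`; shrinking exponential lesions have no finite
formation time and are excluded from the rate fit, flagged.

## Limitations

* Formation-rate estimates with few lesions are saturated or noisy
  (n = 2 is an exact fit); no uncertainty intervals are attached to
  formation times or k.
* The linearized estimator assumes one shared curve; mixed or
  tissue-heterogeneous cohorts surface only through the significance
  test, which with few, noisy intervals has limited power.
* Interval SGR carries the finite-interval attenuation described above;
  it is negligible at the default visit spacing but grows as (λΔt)²/12.
* Only the exponential/Gompertz pair is implemented; the approach
  extends to other decelerating models but none is provided.
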