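# metagrowth

Estimating tumour growth-model parameters and metastasis formation rates
for an **individual patient** from longitudinal volume measurements of
multiple metastases.

## The problem

Clinical imaging rarely observes a tumour long enough to distinguish
exponential growth from decelerating (Gompertzian) growth: over a short
window both curves fit the measured volumes essentially perfectly, yet
their back-extrapolations disagree wildly — formation times can differ by
decades, and the implied growth rate at formation by an order of
magnitude.  The choice of model, not the quality of fit, drives every
downstream quantity: how old each metastasis is, how fast new metastases
appear, and how many (including invisible micro-metastases) are present
at a given time.

`metagrowth` implements an estimator that sidesteps the short-window
problem by pooling lesions.  If all metastases of one type in one patient
follow a *general* Gompertz curve

    V(t) = V0 · exp[ (SGR0/λ) · (1 − e^{−λ(t−t0)}) ],

differing only in when each lesion started, then the specific growth rate
SGR = (1/V)·dV/dt is linear in log volume and **free of time**:

    SGR = SGR0 − λ · ln(V/V0).

So for each pair of consecutive measurements of each lesion one computes
the interval SGR, `ln(V2/V1)/(t2−t1)`, pairs it with the log geometric
mean `(ln V1 + ln V2)/2`, pools these records across *all* lesions —
whose ages need not be known — and fits an ordinary least-squares line:
the slope gives the deceleration constant λ, the intercept (evaluated at
the one-cell volume V0 = 10⁻⁹ cm³) gives SGR0.  A significantly negative
slope selects the shared decelerating model; otherwise the lesions are
treated as exponential growers with heterogeneous rates.

With the general curve in hand, each lesion is dated by sliding the curve
along the time axis to its measurements (the optimal shift is the time
the lesion was one cell), and the ordered formation times yield the
metastasis formation rate k from the through-origin fit
`ln(count) = k · (t − t_first)`.

## Worked example

A single decelerating tumour with SGR0 = 0.001/day, λ = 0.0003/day and
V0 = 1 at t = 0, measured every 180 days for ten years, analysed through
the interval/regression machinery:

```python
from metagrowth import appendix_series, series_to_intervals, fit_sgr_logv

intervals = series_to_intervals(appendix_series())   # 20 consecutive pairs
fit = fit_sgr_logv(intervals, v0_assumed=1.0)
```

prints (via the snippet in `docs/methods.md`):

```
n intervals   : 20
slope         : -0.000299927  ->  lambda = 0.000299927 /day
SGR0 (V0=1)   : 0.000999757 /day
r^2           : 1.000000   p(slope) = 9.5e-179
selected model: general_gompertz
```

The regression recovers the generating parameters to 0.03% — the small
deficit is the exact finite-interval factor `tanh(λΔt/2)/(λΔt/2)` that
relates interval to instantaneous growth rates.  Growth rates convert to
volume doubling times as DT = ln2/SGR; e.g. 1.1 %/day ↔ 2 months and
0.14 %/day ↔ 17 months under the 30-day-month reporting convention.

For a whole-patient analysis from a measurement file
(`lesion_id,time,volume_cm3`, times as days or ISO dates):

```sh
metagrowth analyze measurements.csv -o report.json --tsv summary.tsv
```

or stage by stage: `metagrowth sgr|linfit|fit|formation|rate`.  Synthetic
cohorts with known ground truth come from `metagrowth simulate` or the
`metagrowth.synthetic_data` module.

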