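# Methods

## Model

A hair segment's isotopic value is modelled as the time-lagged environmental
signal plus a constant diet–hair offset:

    hair_i = slope · env_i(ℓ) + Δ + ε_i

* `env_i(ℓ)` — arithmetic mean of the δ³⁴S isoscape value at every GPS fix
  whose timestamp falls in segment *i*'s growth window shifted earlier by the
  lag ℓ (days). Windows and fix membership are half-open `[start, end)`, so
  no fix is ever double-counted across adjacent segments.
* `slope` — fixed, default 1: hair tracks environment one-to-one, which is
  what makes the intercept interpretable as a discrimination factor. The
  intercept has the closed form `Δ̂ = mean(hair − slope·env)`; a property
  test confirms it against a brute-force grid minimiser of SS_res.
* goodness of fit — `r² = 1 − SS_res / SS_tot`, with SS_tot about the mean
  of the hair values. The definition reduces to the ordinary OLS r² when the
  imposed slope equals the OLS slope, and can go negative when the slope is
  badly wrong; it is undefined (NaN, flagged) when the hair values are
  constant. Whether to define r² this way or as a squared correlation was a
  genuinely open choice; this one is isolated in a single function
  (`estimators._fixed_slope`) so it can be swapped.

The lag is selected by scanning a grid (default 0–160 d in 10-day steps,
the physiologically plausible range for a ruminant of this size) and taking
the argmax of r² over lags with ≥ 2 pooled observations. Exact ties break
toward the **smallest** lag — the parsimonious choice, requiring the least
extrapolation before the GPS record begins.

All animals are pooled into one regression with a single intercept.
Between-animal variation in Δ is a separate diagnostic: per-animal
intercepts `Δ̂_a = mean_a(hair − env)` at the selected lag, summarised by
their across-animal SD (n−1). This moment estimator stands in for a mixed
-model random-effect SD; no likelihood machinery is used.

## Segment dating

Net growth rate = total regrown length / days between shave and collection.
Segments are 8 mm; a distal remainder < 8 mm is discarded. Windows are
anchored at the **collection** date: segment *i* spans
`[end − (i+1)·8/rate, end − i·8/rate)`. The proximal date is exact (hair
shaved to skin), while the distal tip may erode, so any mismatch between
`rate · growth_days` and the measured length accrues at the old end; distal
segments that reach before the first GPS fix (after the lag shift — coverage
is always evaluated after shifting) are dropped from the regression with a
logged count.

All window arithmetic routes through one nanosecond-integer function
(`growth.segment_bounds_ns`), so dating, georeferencing and simulation agree
exactly; adjacent windows share their boundary bit-for-bit.

The growth-rate covariate model (rate ~ proportion of growth days in the dry
season + proportion lactating + indicator of growth > 395 d) is an ordinary
least-squares fit via statsmodels; constant covariates are excluded and
flagged, collinear ones raise an error naming the columns. The covariate
coding (proportions of the growth period) is this package's choice — the
original field analysis did not state its coding, so its printed
coefficients are not a reproduction target.

## Bootstrap

Growth rates are the dominant uncertainty. Each of B replicates draws an
independent rate per animal from `Normal(r̄, s_r)` — the mean and n−1 SD of
the cohort's **observed** net rates — truncated to positive values by
redraw (truncation is astronomically rare at the default 0.511 ± 0.062
mm/day but must be defined), re-dates and re-georeferences every segment,
reruns the scan, and records the winning lag and intercept. Reported:
replicate means and equal-tailed percentile intervals, default 2.5–97.5
(a "95th percentile interval"; the pair is configurable since 5–95 is also
in use). The mean of per-replicate argmaxes need not lie on the 10-day
grid. Replicates are driven by one `numpy` Generator seeded from a single
integer: runs are bitwise reproducible for a fixed seed and B.

## Raster conventions

Isoscapes are ESRI ASCII grids (row 0 = northern row). Cell ownership is
half-open `[edge, edge + cell_size)` in both axes, so boundary points are
deterministic; lookup is nearest-cell (no interpolation). Points outside
the extent or on nodata cells yield *missing*, never an error; such fixes
are excluded from the windowed mean rather than imputed — the realistic
treatment for animals ranging beyond a predicted isoscape. Coordinates are
planar map units; no geodesy is performed because the analysis only needs
point-in-cell lookup.

## Reference table conventions

The shipped 11-animal growth table reproduces its source's display
conventions, which matter when re-deriving its summary: per-animal rates are
**truncated** (not rounded) to 3 decimals, and the cohort SD uses the
population (n) denominator before truncation — that is the only convention
under which the printed mean 0.511 and SD 0.062 follow from the printed
dates and lengths. The API-level `summarize_rates` uses the conventional
n−1 sample SD; `printed_summary` applies the table conventions.

## The synthetic generator

`SimConfig` defaults encode the study conditions the estimator targets:

| parameter | default | meaning |
|---|---|---|
| `rate_mean`, `rate_sd` | 0.511, 0.062 mm/d | cohort growth-rate distribution |
| `grass_sd_permil` | 1.21 ‰ | site-level grass δ³⁴S SD, drawn per GPS fix |
| `analytical_sd_permil` | 0.65 ‰ | per-segment measurement SD |
| `true_lag_days` | 80 d | on the 10-day scan grid |
| `true_fractionation_permil` | 2.1 ‰ | diet–hair offset (typical small positive value) |
| `fractionation_sd_permil` | 0 ‰ | optional animal-level spread of the offset |
| `isoscape_range` | (−5, 30) ‰ | clipping range of the field |
| gradient | 13 → 2 ‰ south→north | spans the measured grass range |
| `duration_days` | 420 | shave→collection, ~14 months as in the field |
| `fix_interval_days` | 1 | daily GPS fixes |
| cohort | 5 migratory + 6 resident | the field design |

Noise placement mirrors where each SD arises physically: grass-level noise
per fix (site–time variation of forage), analytical noise once per segment
(one mass-spec measurement per section). The lag is a pure time shift
(single-spike kernel); distributed kernels are an extension point, not the
default, because the estimator assumes a single lag. Migrants follow a
sinusoidal annual north–south oscillation spanning the gradient with
Ornstein–Uhlenbeck jitter; residents are an OU walk hard-clipped to a disc.
The simulated year is 365 days with a five-month June–October dry season
and February-calving/September-weaning lactation for covariate tests.

What the simulator does **not** emulate: real geography or rainfall,
behaviourally mechanistic movement, seasonally varying diet quality (which
in real ungulates modulates both fractionation and effective lag),
distributed lags, isoscape prediction error structure, or GPS fix dropout.
Passing recovery tests therefore demonstrates that the *estimator* is
correct and well-behaved under the assumed data-generating process — not
that a single fixed lag is the right physiological model for any particular
species.

## Problem sizes and numerical checks

Tests and the acceptance script run a 5-migrant cohort (~25 segments each,
~126 pooled observations) with B = 500 bootstrap replicates — enough for
percentile intervals at the scan's 10-day resolution; production runs
default to B = 5000. Noiseless recovery is asserted to 1e-9 (exact up to
floating accumulation); stochastic recovery to one grid step (±10 d) for
the lag and ±0.3 ‰ for the fractionation, with intervals covering truth.
Directional checks mirror the estimator's known sensitivities: dating with
a faster assumed rate never lowers the selected lag, and imposing slopes
0.75 / 1.0 / 1.25 orders the selected lags non-decreasingly.

## Known limitations

* Observed net rates (floor-to-8 mm length over duration) slightly
  underestimate true growth, giving synthetic bootstrap lag means a small
  (~5 d) downward tendency — the same mechanism by which distal erosion
  biases field net rates; it stays well inside one grid step.
* The per-individual SD diagnostic is a moment estimator; with few animals
  its sampling band is wide (a chi-square band at n = 6 spans roughly half
  to 1.6× the true SD).
* Fixes are point samples; no interpolation between fixes and no
  utilisation-distribution weighting of the isoscape.
* The lag grid is discrete; a single scan cannot resolve lags finer than
  its step, and only the bootstrap mean interpolates between grid points.
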