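# Methods

This note documents the statistical model behind `saxsqc`, the estimators it
uses, the tunable parameters and their defaults, what the synthetic data do
and do not emulate, and the numerical choices made where the design was
genuinely open.  Every number quoted here is recomputed by the test suite or
by `scripts/acceptance.py`; none is asserted from memory.

## The trend-test model

Every quality call reduces to the same primitive: a SAXS parameter y
(R_g, I(0), D_max, χ², Porod MW) observed at n values of an abscissa x
(exposure number for damage, relative concentration scale for interference)
is fit by ordinary least squares, and the slope a is tested with
t = a/s_a on n−2 degrees of freedom, s_a taken from the residual variance.
Two-tailed p-values come from the continuous Student-t CDF (regularized
incomplete beta), not from a lookup table.  p ≤ 0.05 is called a probable
trend (red), 0.05 < p ≤ 0.20 possible (yellow), p > 0.20 unlikely (green).

The model assumes Gaussian, independent, homoscedastic parameter noise.
Violations (frame-to-frame correlation, non-Gaussian discretization noise)
generally inflate the false-positive rate — a conservative failure mode for
a screen whose job is to protect the averaged curve.  The test suite
verifies the calibration directly: under a no-drift null with Gaussian
noise the red rate is 0.05 ± 0.02 over 2000 replicates.

Degenerate fits are resolved by the limits of the t statistic: zero
residuals with a nonzero slope give p = 0 (an exact trend is certainly a
trend); a perfectly flat response gives t = 0, p = 1.  Exactness is decided
at 1e-10 relative to the response scale.

Raw per-parameter p-values are reported; no multiple-testing correction is
applied across the 5 (damage) or 10 (concentration) parameters.  Series-
level summaries therefore count colors rather than pooling p-values, and
the validation studies use "≥ 3 of 10 red" as the series-level interference
call (measured: 3.3% of ideal series trip it; hard-sphere series at
φ = 0.02–0.08 trip it essentially always).

## Radiation-damage screening

Five parameters are tracked per exposure series: Guinier R_g and I(0)
(from the Shannon-bounded region, falling back to the full low-q region
when that region is too sparse), R_g and D_max from P(r), and the reduced
χ² of each frame against the first (lowest-dose) frame,

    χ² = (1/n) Σ_i (I_1(q_i) − I_2(q_i))² / (σ_1,i² + σ_2,i²),

with both error columns combined in quadrature and ν = n (no fitted
parameters).  This convention makes E[χ²] exactly 1 for two independent
realizations of one curve — the calibration the test suite checks — and 0
for identical profiles.

Frame filtering has three stages, in order:

1. **Outlier screen** — modified z-score M = 0.6745·(x − median)/MAD with
   cutoff 3.5, applied to the P(r)-route R_g only (the most robustly
   determined parameter).  A zero MAD (a majority of identical values)
   flags any deviating value.  The screen exists because the trend test
   cannot isolate step-like jumps: dropping the last frame of a stepped
   series leaves a hump that inflates the residual variance and stalls the
   rejection loop.  It is disabled for concentration series, where all
   members are needed.
2. **Trend test** per parameter against frame number.
3. **Sequential rejection** — while p < 0.05 and ≥ 3 frames remain, the
   highest-dose frame is dropped and the fit recomputed; exhausting to
   < 3 frames rejects the whole series.  A frame rejected for *any*
   parameter is excluded from averaging.

Survivors are averaged pointwise with inverse-variance weights
(σ_out = (Σσ_i⁻²)^(−1/2)).

## Guinier analysis

R_g and I(0) come from the line through (q², ln I) over the Guinier regime
q < 1.3/R_g: R_g = (−3·slope)^½, I(0) = exp(intercept), errors propagated
from the fit covariance.  Three regions are fit, all ending at 1.3/R_g with
R_g taken from P(r): region 1 starts at the first measured point, region 2
at the information-theoretic bound π/D_max, region 3 at 0.65/R_g.  Regions
with fewer than 5 points (the minimum for the linearity test below) are
reported absent.  A standalone iterated fit (region updated from the fitted
R_g until the change is < 1%, up to 10 cycles) seeds the D_max search.

**Known systematic.**  For a homogeneous sphere the form-factor expansion
gives ln F² = −x²/5 − x⁴/350 (x = qR), so any least-squares line fit out to
q·R_g = 1.3 overestimates R_g by ≈ +2.0% (narrower, higher-q regions are
worse: ≈ +4% for region 2 on a 30 Å sphere).  This is a property of the
Guinier approximation at its conventional validity limit, not of the
implementation; the P(r)-route R_g does not share it (< 0.1% error on the
same data).  Trend *detection* is unaffected — a constant bias common to
all members cancels in the slope.

**Linearity ("slope of slopes").**  Within each region the OLS slope of
every 3-point window of (q², ln I) is computed, windows advancing one point
at a time, and the slopes are regressed on their windows' mean q².  Exactly
linear data give identical slopes and p = 1.  A significant positive trend
(slopes rising with q², i.e. extra intensity at the lowest q) is reported
attractive; negative, repulsive.  Overlapping windows make neighboring
slope errors strongly negatively correlated; the plain t-test is applied
anyway, which in practice is conservative (measured null flag rate ~0 at
α = 0.05), at some cost in power.  Consequently the screen resolves a trace
aggregate (3% by mass of a 3× sphere) reliably on 8-frame averaged
profiles (≈ 0.35% noise; 100% detection in the validation study) but not on
single 1%-noise frames.

## Indirect Fourier transform and D_max

P(r) is expanded as r·Σ a_k sin(kπr/D_max) (zero at both ends by
construction) and fit to I(q) through the standard transform
I(q) = 4π∫P(r)·sin(qr)/(qr)dr, discretized by trapezoid on a 201-point
r grid.  The number of basis functions is ceil(N_s) + 5 where
N_s = (q_max−q_min)·D_max/π is the Shannon-channel count — the information
content of the data bounds the model's freedom.  Coefficients solve the
σ-weighted normal equations with a second-difference (curvature) penalty on
P(r); the penalty weight is alpha × trace ratio of the data and penalty
normal matrices, with alpha = 1e-5 by default, chosen so that noiseless
sphere fits stay at χ² ≪ 1 while 1%-noise fits remain smooth.  An
ill-conditioned system retries once at 10× alpha.

D_max candidates span [2, 5]·R_g around the classical 3.5·R_g starting
guess, R_g seeded by the iterated Guinier fit.  Candidates sit on a fixed
absolute 2.5 Å grid rather than a seed-relative one: repeat measurements of
one sample then score identical candidate values, so discretization error
is common-mode across a series instead of entering the trend tests as
per-member jitter (with seed-relative candidates the D_max null red rate
was ~17% instead of ~5%).  Each candidate is scored by

    w₁·max(0, χ²−1) + w₂·(fraction of P < 0) + w₃·TV(P)/(2·max P)
    + w₄·(|P| mass in the last 5% of r),      w = (1, 2, 1, 1),

penalizing misfit, negativity, oscillation (the total-variation term equals
1 for a clean single peak) and mass piled at the boundary; the minimum
wins.  R_g and I(0) follow from the moments R_g² = ∫r²P dr / 2∫P dr and
I(0) = 4π∫P dr (trapezoid).

## Porod analysis

Q = ∫q²(I−k)dq over the measured range plus the analytic tail K/q_max
(assuming exact q⁻⁴ decay beyond the data; on by default), V = 2π²·I(0)/Q
with I(0) from the P(r) route, MW = 0.82503 Da Å⁻³ × V (1.37 g cm⁻³).

The flat background k is subtle for compact particles because q⁴I
oscillates about its asymptote with period ≈ π/R in q: a straight-line fit
of I·q⁴ vs q⁴ over an arbitrary window reads the oscillation phase as a
slope.  When R_g is available the background is instead estimated from the
difference of the period-averaged means of q⁴I over the last two full
oscillation periods, which cancels the oscillation; K is the last period's
mean.  If only one period fits in the measured range no background is
attempted (data are assumed background-subtracted) — a documented
limitation for small particles on short q ranges.  The plain tail-fraction
OLS (default 0.25) remains as the fallback when no R_g is known.  With
this estimator a 0.01 background on a unit-I(0) sphere is recovered to
±5%, and sphere volumes for R = 15–50 Å are within ~1.5% of 4πR³/3 with
< 1% drift when q_max is truncated from 0.35 to 0.25 Å⁻¹.

## Concentration series

Members are scaled to the first (lowest) concentration by the median ratio
over 50 points starting at the first grid point ≥ 0.07 Å⁻¹ — low enough q
for signal, high enough to be insensitive to weak interference; both
numbers are config-overridable since they are instrument-specific.  The
median makes the scale robust to isolated corrupted points; its standard
error at 1% point noise is ≈ 0.25%.  The scale factors are the regression
abscissae (first member ≡ 1); members are divided by their scale before
parameter extraction, so parameters are per unit concentration.

Ten parameters are tested: R_g and I(0) from P(r) and from each Guinier
region, D_max, and the Porod MW.  Impact = |slope|/|intercept| × 100 per
unit abscissa; when a calibration constant is supplied (intensity per
(mg ml⁻¹·Da)), concentrations are estimated as c = I(0)/(calib·MW) and
impacts converted to % per mg ml⁻¹ via the series' abscissa-to-
concentration span ratio, anchored on the estimated concentrations — an
estimate only as good as the calibration (~10% for water/standard
calibrations).

## The synthetic-data generator

What it emulates: analytic sphere and prolate-ellipsoid form factors
(ellipsoids by 128-point Gauss–Legendre orientational averaging); a
Percus–Yevick hard-sphere structure factor of tunable volume fraction
(S(0) = (1−φ)⁴/(1+2φ)², correlation peak near 2π/2R); geometric per-frame
growth of radius and forward intensity as the damage phenomenology; trace
aggregates as a mass fraction of a larger sphere weighted by the volume
ratio (forward scattering per particle ∝ V², which is why tiny mass
fractions dominate low q); serial dilutions with optional relative errors
in the dilution factor; Gaussian noise σ(q) = f·I(q) + floor with the true
σ written to the error column.  Default grid 0.01–0.35 Å⁻¹, 500 points;
defaults f = 1%, 8 frames, 30 Å sphere.

What it does not emulate: Poisson counting statistics, inter-frame
correlated noise, buffer-subtraction errors, beam smearing, detector
artifacts, or chemically detailed damage kinetics.  Passing tests
therefore demonstrate that the statistics are calibrated and the
estimators recover known ground truth under idealized Gaussian conditions
— not that real beamline data meet those conditions.  Because the σ column
is exact, χ² calibrations are sharper than on real data, where error
estimates are themselves uncertain.

The Gaussian choice (rather than Poisson) is deliberate: the χ² comparison
and the t-tests assume Gaussian errors, and the generator's job is to test
the statistics under their own model; at typical SAXS count rates the
difference is negligible.

## Validation studies and problem sizes

`saxsqc.validation` packages the end-to-end studies; the acceptance script
and `tests/test_acceptance.py` run them at these sizes: 100 profile pairs
for the χ² mean; 2000 replicates for the type-I rate; 100 series for
damage power (2%/frame drift, 1% noise); 50 seeds for sphere parameter
recovery; 20 series for scaling accuracy; 100 seeds for the
trace-aggregate screen; 50 + 50 series for the interference flag rates.
These sizes put the Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping a full run in the low minutes on one
core.

## Known limitations

- Guinier R_g carries the intrinsic ≈ +2% sphere bias at the q·R_g = 1.3
  limit (above); elongated or disk-shaped particles would need the
  cross-section Guinier variants, which are out of scope.
- D_max is resolved to the 2.5 Å candidate grid; the quality score is an
  analogue of, not a match to, the perceptual criteria of established IFT
  packages, so absolute D_max values need not agree with theirs.
- Porod background detection requires ≥ 2 oscillation periods in the
  measured range; MW assumes globular density 1.37 g cm⁻³.
- The concentration-to-mg ml⁻¹ conversion inherits the ~10% calibration
  uncertainty; without a calibration constant impacts are per unit
  relative scale.
- With only 3 concentrations the trend test (df = 1) has limited power;
  the breadth of the 10-parameter panel, not per-test power, carries the
  detection.
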