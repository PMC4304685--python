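# saxsqc

Statistical quality assessment of small-angle X-ray scattering (SAXS) data.

Solution SAXS measures a 1-D intensity profile I(q) from which the key
low-resolution parameters of a macromolecule are derived: the radius of
gyration R_g, the forward scattering I(0), the maximum dimension D_max, the
pair-distance distribution P(r) and the Porod volume/molecular weight.  Two
experimental artifacts silently corrupt these numbers: **radiation damage**
accumulating over consecutive exposures, and **interparticle interference**
growing with sample concentration (the structure factor S(q) deviating from
unity).  Historically both were judged by eye.

`saxsqc` makes those judgements statistical.  For every SAXS parameter y
measured across an exposure series (or a dilution series) it fits ordinary
least squares y = a·x + b and tests the slope with

    t = a / s_a ,   df = n − 2 ,   p = 2·(1 − CDF_t(|t|, df)),

calling a trend *unlikely* (green, p > 0.20), *possible* (yellow,
0.05 < p ≤ 0.20) or *probable* (red, p ≤ 0.05).  Around that engine it
implements:

- **Radiation-damage screening** — five parameters per exposure series
  (Guinier R_g, P(r) R_g, I(0), D_max, and the reduced χ² of each frame
  against the first); outlier frames removed by the modified z-score of the
  P(r) R_g (cutoff 3.5), significant trends resolved by sequentially
  rejecting the highest-dose frames, survivors averaged with
  inverse-variance weights.
- **Guinier analysis** over three regions all ending at q_max,G = 1.3/R_g
  (R_g from P(r)): region 1 from the first measured point, region 2 from the
  Shannon bound π/D_max, region 3 from 0.65/R_g — plus a sliding-window
  "slope of slopes" linearity test whose sign separates attractive from
  repulsive interactions.
- **Indirect Fourier transform** to P(r) with automatic D_max selection
  (sine-series expansion, smoothness-regularized, candidates scored on fit
  quality, negativity, oscillation and tail weight).
- **Porod analysis** — invariant Q = ∫q²(I−k)dq with analytic q⁻⁴ tail
  extension, volume V = 2π²·I(0)/Q, molecular weight at 1.37 g cm⁻³
  (0.82503 Da Å⁻³).
- **Concentration-dependence testing** — each dilution member is put on a
  relative scale (median intensity ratio over 50 points from q = 0.07 Å⁻¹)
  and ten parameters (4×R_g, 4×I(0), D_max, Porod MW) are regressed against
  those abscissae; impacts are reported in % per mg ml⁻¹ using
  concentrations estimated from a calibration constant.
- **A synthetic-data generator** (spheres, prolate ellipsoids, Percus–Yevick
  hard-sphere structure factor, per-frame damage drift, Gaussian noise with
  reported σ) so the whole pipeline is testable without beamline data.

## Worked example

Simulate a clean three-concentration sample of a 30 Å sphere (8 exposures
per concentration, 1% noise, ideal S(q) = 1), then analyze it:

```bash
saxsqc simulate --out demo --seed 5 --radius 30 \
    --volume-fractions 0.001,0.002,0.005 --no-structure-factor
saxsqc analyze --manifest demo/manifest.yaml --out demo_report
saxsqc report --report-dir demo_report
```

which prints:

```
sample_1:
  radiation c1: absent=0 green=3 red=0 yellow=2
  radiation c2: absent=0 green=2 red=0 yellow=3
  radiation c3: absent=0 green=5 red=0 yellow=0
  concentration: absent=0 green=7 red=0 yellow=3
  median impact: 0.02 (percent_per_abscissa)
```

No parameter is red: neither radiation damage (no drift was simulated) nor
concentration dependence (the structure factor was ideal) is probable, and
all eight frames survive to the average at every concentration.  The yellow
slots are the expected noise at these thresholds — under a true null,
p ≤ 0.20 occurs for a fifth of the parameters.  The median impact says
that, trends or not, a unit change of relative concentration shifts a
typical parameter by only 0.02% (reported per mg ml⁻¹ instead when the
manifest carries a `calibration_constant`).  Per-parameter slopes,
p-values and kept frames are in `demo_report/radiation_report.csv` and
`concentration_report.csv`.  If a 2% per-frame radius drift is injected
(`--rg-drift 0.02`), all five damage parameters turn red and every frame is
rejected — the drift is dose-correlated all the way back to the first
exposure.  The same analysis is available in Python via
`saxsqc.pipeline.run_sample`.

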