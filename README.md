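# dropletlab

Quantitative image and curve analysis for biomolecular condensates formed by
liquid–liquid phase separation (LLPS), aimed at in-vitro droplet experiments
with two fluorescently labeled proteins (e.g. a green-labeled scaffold and a
red-labeled partner) under macromolecular crowding.

The package covers the full measurement chain of such a study:

- **Synthetic data with ground truth** (`synthgen`): two-channel droplet
  scenes with configurable core–shell enrichment, uniform bead fixtures,
  dye calibration fields, FRAP traces, a finite-difference FRAP diffusion
  simulator, rotor-dye fields and turbidity grids. Every generator records
  its ground truth, so each analysis stage can be validated by round trip.
- **Droplet segmentation** (`segment`): per-slice min–max normalization of
  both channels, iterative detection seeded at the brightest unassigned
  channel-1 pixel (stopping when the peak drops below 75% of the slice
  maximum), flood fill to half-maximum, watershed splitting of touching
  droplets, and circularity validation (4πA/P²).
- **Radial core–shell profiling** (`radial`): secondary normalization of the
  droplet crop, intensity sampling along n equally spaced rays (default 30)
  from the center to 1.2× the radius, ray-averaged profiles with s.d.
  envelopes, channel-ratio traces and a scalar shell-enrichment statistic.
- **FRAP** (`frap`): photobleaching correction, nonlinear fitting of the
  hyperbolic recovery model `I(t) = (I0 + I∞·t/t½)/(1 + t/t½)`, mobile
  fraction `Mf = (I∞ − I0)/(1 − I0)`, apparent diffusion coefficient
  `D_app = 0.224·r²/t½`, and prediction of recovery under a hypothetical
  viscosity fold-change (t½ scaled ∝ viscosity).
- **Concentration quantitation** (`quant`): linear dye calibration with an
  R² ≥ 0.95 linearity gate, intensity → total protein concentration via
  labeled-fraction dilution and quantum-yield correction factors (defaults
  0.73 green / 1.43 red), molar ratios, partition coefficients, light-phase
  concentrations from plate-reader standards, and bleach-corrected
  time-lapse composition traces.
- **Rotor viscometry** (`visco`): a glycerol/water viscosity oracle (Cheng
  mixture formula), Förster–Hoffmann power-law standard curves for a
  molecular rotor dye (DCVJ-like), and droplet viscosity estimation.
- **Phase diagrams** (`phases`): turbidity scoring (positive at A340 ≥ 0.1)
  and Pareto-minimal phase-boundary extraction over (protein A, protein B,
  crowder) grids.

## Worked example

`examples/02_frap_fitting.py` generates recovery traces at two crowding
conditions, re-fits them, and evaluates the viscosity-scaling argument:

```
no crowder: Mf = 0.790, t_half = 14.30 s, D_app = 3.92e-03 um^2/s
5% crowder: Mf = 0.270, t_half = 22.50 s, D_app = 2.49e-03 um^2/s
100-fold viscosity, 10-min window: 23.3% recovery
```

The fitted mobile fraction and half-time reproduce the generating
parameters exactly on noiseless traces. The last line answers a mechanistic
question: if the only effect of crowding were a 100-fold viscosity increase,
the model still predicts ~23% recovery within 10 minutes — so a measured
mobile fraction far below that implies formation of a cross-linked protein
network rather than simple slowing of diffusion.

The other examples each exercise one capability end to end and print the
recovered value against its generator ground truth: core–shell profiling
with a bead control (`01`), concentration ratios through the full
calibration chain (`03`, recovering a 10:1 dense-phase stoichiometry),
rotor viscometry (`04`) and phase-boundary extraction (`05`).

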