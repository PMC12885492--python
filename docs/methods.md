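# Methods

## The estimation problem

A pair of clamp-on transmission sensors shine 680 nm and 850 nm laser light
through blood-filled tubing and read the transmitted intensity with a
photodiode behind a pulse-summing analog front end.  Deoxygenated
hemoglobin absorbs more strongly at 680 nm, oxygenated hemoglobin more
strongly at 850 nm, so the two channels jointly encode oxygen saturation
(SO2) and total hemoglobin concentration (Hgb).  Because whole blood
scatters light at a strength comparable to absorption (the sub-diffuse
regime), analytic inversion is unreliable and the package calibrates
empirically against paired blood-gas-analyzer (BGA) references.

## Preprocessing

* **Pulse normalization.** The front end sums up to 127 laser pulses into
  one 16-bit ADC reading; counts are divided by the pulse number, making
  intensities comparable across front-end settings.
* **Windowing.** Each blood sample is paired with the mean normalized
  intensity over the preceding one-minute, 20 Hz recording.  The mean is
  unweighted and no outlier rejection is applied; the bench procedure
  waits out all transients before recording, so the window is stationary
  by design.
* **Cross-sensor scaling.** For each wavelength, every sensor's intensities
  are multiplied by (grand mean across sensors) / (that sensor's mean),
  computed on the calibration split only.  This removes fixed
  manufacturing gain differences so a single calibration curve serves all
  devices.  The reference is the symmetric grand mean rather than an
  arbitrarily privileged sensor.  The scaled intensities feed *both* model
  stages, including the ratio R = ln(I680)/ln(I850).
* **Degenerate guard.** R is undefined when ln(I850) vanishes; windows with
  |ln(I850)| ≤ 1e-6 are rejected.  Normalized counts-per-pulse in realistic
  operation sit far from 1, so the guard only fires on corrupt input.

## Stage 1: hemoglobin

The nine-term library [(ln I680)², (ln I850)², R², ln I680, ln I850, R,
ln I680·ln I850, ln I680·R, 1] is deliberately kept exactly as designed —
including the asymmetry that ln I850·R is absent.  Non-constant terms are
standardized (zero mean, unit variance); the elastic-net objective

    (1/2n) Σ (y − Xw − a9)² + λ [ mix Σ|w| + (1−mix)/2 Σ w² ]

is minimized with (λ, mix) selected by 5-fold cross-validated MSE over a
50-point logarithmic λ ladder (1e-5…1) crossed with mix ∈ {0.1, 0.5, 0.9};
fold assignment is seeded and ties resolve to the smaller λ, then the
smaller mix.  Coefficients are reported de-standardized so a1…a9 apply to
raw library terms.  λ = 0 dispatches to exact least squares (numpy
``lstsq``) rather than coordinate descent, so the unpenalized fit agrees
with the normal equations to machine-level precision; a singular design at
λ = 0 raises a rank-deficiency error instead of silently returning a
minimum-norm solution.  Hemoglobin predictions are never clamped —
out-of-range values are a calibration failure that should stay visible.

## Stage 2: saturation

Calibration samples are assigned to integer-g/dL bin centers (nearest
center, ties to the lower center, ±0.5 g/dL halfwidth, ≥3 samples and
non-degenerate R variance per retained bin; ≥2 retained bins required).
Within each bin, OLS of SO2 on R gives (alpha_j, beta_j, r²_j); unweighted
OLS of alpha_j and beta_j on the bin centers gives the linear
concentration corrections.  Binning uses the BGA reference Hgb during
calibration; inference uses the stage-1 estimate, as deployed hardware has
no reference.  SO2 is clamped to [0, 100] with a flag, since saturation is
physically bounded.

The stage-2 linear-in-Hgb correction is an approximation, not an identity:
for any transmission model in which attenuation grows linearly with Hgb,
the per-bin slope alpha(Hgb) has the form B/Hgb + A, so a straight line in
Hgb carries a structural residual (the generator's bin slopes fit a line
with R² ≈ 0.94 over 6–14 g/dL).  End-to-end on noiseless synthetic data
this leaves an SO2 RMSE of ≈ 2.2 % — an intrinsic floor of the two-stage
estimator itself, of the same order as the few-percent saturation errors
seen on real bench data — while hemoglobin, which is exactly affine in the
two log-intensities under the forward model, recovers to numerical
precision (≈ 4e-5 g/dL).

## Synthetic bench experiment

The generator collapses the bench loop's settling dynamics to equilibrium
samples:

* **Forward model.** ln I = ln(gain) − path·[eps_mix(SO2) + mu_s]·Hgb per
  wavelength, the modified Beer–Lambert form above.  Defaults: compiled
  hemoglobin molar extinctions converted to per (g/dL)·mm via ln(10)/64500
  (680 nm: Hb 0.0939, HbO2 0.0105; 850 nm: Hb 0.0247, HbO2 0.0378),
  effective scattering 0.033/0.030 (well below textbook reduced scattering
  because the contact detector collects forward-scattered light), and a
  7.5 mm path (3/8-inch tubing bore minus the 2 mm clamp compression).
  Sensor gains (1.60e5/1.65e5 and 1.90e5/1.38e5) differ by 15–20 % between
  devices, emulating manufacturing spread; their magnitudes place both
  log-intensities comfortably away from the ratio singularity over the
  whole protocol grid.
* **Protocol.** 86 samples over 7 days; Hgb levels 6…14 g/dL round-robin
  across days; SO2 swept 50 → 100 % in 10 % steps within each level (the
  bench procedure oxygenates stepwise, then dilutes); per-day counts as
  even as possible with the remainder on the earliest days.  The paper-gap
  choice of per-day allocation is free and fixed here once.
* **Noise.** Multiplicative log-normal intensity noise (sigma 0.005 per
  window) and Gaussian BGA reference noise (0.1 g/dL, 0.5 %), truncated to
  physical ranges — the smallest model producing bench-magnitude errors.
  All draws come from one seeded generator in a fixed order, so a seed
  fully determines the dataset.
* **Raw stream (optional).** A 20 Hz ADC time series can be emitted by
  repeating each equilibrium value with fresh per-point noise, choosing a
  per-(sensor, day, wavelength) pulse number that fills the 16-bit range —
  mimicking how the front end is retuned between concentration levels —
  and applying a fixed front-end scale of 0.02 counts per model unit.
  Constant per-channel factors of this kind are exactly what the sensor
  scaling and calibration absorb.

What the generator does **not** emulate: settling transients and flow
pulsatility, temperature dependence of blood optical properties,
hematology beyond total hemoglobin (cell shape, plasma composition),
tubing-material variation, and any Hgb-dependent *systematic* sensor error.
Synthetic accuracies are therefore optimistic relative to the bench: they
validate the calibration machinery (scaling, model selection, two-stage
correction, statistics), not the physical sensor.

## Statistics

MAD = Σ|s_i − b_i|/n and ARMS = sqrt(Σ(s_i − b_i)²/n) over prediction/
reference pairs; Bland–Altman bias ± 1.96·sd (sample sd, n−1; no
small-sample t correction); per-day MADs by grouping pairs on day id.  R²
is computed against the identity line, 1 − Σ(s−b)²/Σ(b−mean b)² — a pure
accuracy measure that penalizes bias and can go negative — with the
squared-Pearson alternative behind a switch.  Adjusted R² uses
1 − (1−R²)(n−1)/(n−p−1) with p = 8 for hemoglobin (non-constant library
terms) and p = 4 for saturation (the four stage-2 coefficients).

## Reproducibility and problem sizes

One top-level seed is split (via numpy ``SeedSequence``) into named
substreams for simulation, the day-stratified 50/50 calibration/validation
split, and CV fold assignment; the full pipeline is byte-identical across
reruns.  All shipped analyses run at the study's native scale — 86 samples,
two sensors, 150 (λ, mix) grid points × 5 folds — and complete in seconds.

## Known limitations

* The stage-2 linear correction's structural residual (above) bounds
  noiseless SO2 recovery at the percent level; an isosbestic third
  wavelength, not implemented here, would remove most of it.
* Bin centers are integers; data concentrated between centers can leave
  sparsely populated bins, and fewer than two usable bins is an error
  rather than a fallback.
* The identity-line R² convention differs from the squared correlation
  some instrument studies report; comparisons across conventions are not
  meaningful.
* Validation statistics treat the BGA reference as noiseless; its noise
  inflates apparent sensor error slightly.
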