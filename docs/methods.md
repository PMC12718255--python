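# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `porinflux`, in the order the pipeline applies them.

## Geometry and encapsulation

A polymersome batch is described by its intensity-weighted z-average
diameter (DLS), vesicle count per mL (nanoparticle tracking), membrane
thickness (default 14 nm for PMOXA₁₅–PDMS₆₈–PMOXA₁₅) and a mean
porin-trimer occupancy from gel densitometry. The lumen volume is the
volume of the inner sphere, $V = \tfrac43\pi(d/2 - r_M)^3$, zero when
the membrane fills the sphere (the ~28 nm micelle population removed by
SEC has no lumen). Encapsulation is treated as statistical: the expected
enzyme count per vesicle is $V c N_A$ with the applied rehydration
concentration $c$ (5.26 µM, consistent with 0.1 mg/mL at ~19 kDa), and
is deliberately kept a real number — it is the mean of a Poisson-like
loading process, and all downstream formulas are mean-field. A
mass-concentration variant divides by the molecular mass first; the two
conventions agree for the reference numbers. The polydispersity index is
carried as metadata only; the size distribution is not modelled.
Membrane thickness is a field rather than a constant because recomputed
per-vesicle counts sit 1–4% from the reference values, consistent with a
slightly different effective thickness; tolerance-based tests absorb
this. The Avogadro constant is fixed at its exact SI value.

## Flash-decay extrapolation

Free GLuc peaks ~1 s after injection, but the plate reader first samples
at 2 s. Each calibration trace (5 points, 2–10 s) is fitted to
$y = a e^{-k_1 t} + b$ by bounded least squares (trf, jacobian scaling,
`xtol` 1e-13, at most 200 function evaluations) with a log-linear
initial guess, and evaluated at t = 1 s. Two numerical points matter:

* a constant trace makes the three parameters unidentifiable; it is
  returned flagged as `a = 0, k1 = 0, b = mean` rather than fitted;
* on slowly decaying traces the split between amplitude and offset is
  poorly identified while the *extrapolated total level* is well
  determined. The calibration pipeline therefore subtracts the known
  instrument baseline (buffer-only wells, default 110 a.u.) from the
  extrapolated level instead of trusting the fitted offset.

## Hill calibration

Peak intensity versus in-well substrate concentration is fitted to
$v = v_{max} c^h/(K_{0.5}^h + c^h)$ by unweighted nonlinear least
squares on the replicate means (initial guesses: $v_{max}$ = 1.2 × max
response, $K_{0.5}$ = median concentration, $h$ = 1; $h$ bounded to
[0.1, 10]). $r^2$ is computed against the mean-response total sum of
squares. 95% CIs come from a nonparametric bootstrap that resamples
replicates within each concentration (default 1000 resamples, seeded;
`n_bootstrap=0` skips them where only point estimates are needed). With
three replicates per concentration the replicate bootstrap undercovers
somewhat; the tests assert majority coverage rather than nominal 95%.
Calibration concentrations are interpreted as final in-well values, the
same convention as the 80 µM assay concentration. The inversion
$c_S = K_{0.5}(v/(v_{max}-v))^{1/h}$ is exact below $v_{max}$; signals
at or above $v_{max}$ raise a saturation error rather than extrapolate.

## Forward simulator

One representative vesicle is scaled by the vesicle count (mean-field).
Its lumen concentration obeys

$$\dot c = \frac{k_T\, n_{tri}}{V_{lumen} N_A}
  + k_{bg}(c_{out} - c) - k_{cat}\, c_E\, f\, H(c), \qquad
  \dot f = -p_{inact}\, k_{cat}\, H(c)\, f,$$

with $H$ the Hill fraction, $f$ the active enzyme fraction and
$c_E$ the lumen enzyme concentration. Well intensity is
`baseline + photon_scale · φ · (total turnovers/s in the well)`, φ the
substrate's relative quantum yield. Integration uses LSODA with
relative tolerance 1e-8 and absolute tolerance 1e-12 on concentrations
(µM); a co-integrated consumption state provides the photon-conservation
oracle. Design choices:

* **Mean-field, not per-vesicle Poisson.** The ≤ 1 trimer per vesicle
  design makes per-vesicle stochasticity second order for the mean
  signal the pipeline analyses.
* **Background permeation** of the bare polymer membrane is reduced to
  two parameters: a first-order equilibration $k_{bg}(c_{out}-c)$
  (default 2·10⁻⁴ s⁻¹) plus an instantaneous defect burst (default
  0.2 µM). The defaults were chosen once so the control trace shows a
  small early bump and a plateau a few percent of the porin signals —
  the qualitative shape of measured controls; no result depends on
  their specific values, which real data would constrain.
* **Inactivation probability** $p_{inact}$ defaults to 1e-3 per
  turnover, putting the free-enzyme flash half-life at tens of seconds.
  In the vesicle regime the quasi-steady state makes the emitted rate
  track the influx, so the plateau is insensitive to $p_{inact}$.
* **Intensity gauge.** `photon_scale` defaults to
  $v_{max}/(k_{cat} N_{cal})$ so a saturated calibration well at the
  calibration enzyme amount (2.5 pmol) emits exactly the reference
  $v_{max}$ — simulator and calibration share one gauge.
* Porin orientation is ignored (random insertion averages out for
  neutral solutes); the outer reservoir is treated as infinite; the
  closed-form steady state $c_{ss} = K_{0.5}(\rho/(1-\rho))^{1/h}$ with
  $\rho = k_T n_{tri}/(k_{cat} N_{GLuc})$ requires $\rho < 1$, the
  assay-sensitivity condition.

## Synthetic data

The generators emulate the statistical structure of plate-reader
exports: long-format tables at 2 s cadence (calibration: 2–10 s; assay:
2–600 s), triplicates, and a truth manifest that round-trips through
YAML. Noise is one multiplicative log-normal factor per replicate trace
at the requested CV — replicate scatter in plate luminescence is
dominated by pipetting and well effects and scales with the signal —
plus additive per-point baseline jitter (sd 5 a.u.). With `noise_cv=0`
all noise is disabled so the noiseless identities hold exactly. The
calibration generator anchors each flash amplitude so the extrapolated
1 s peak equals the Hill truth at that concentration, i.e. the Hill
parameters are defined at the peak, which is also how the calibration
model reads them back. Randomness derives from one global seed expanded
into per-trace substreams keyed by a CRC of the condition label, so
adding a scenario never changes another scenario's bytes.

What the generator does **not** emulate: instrument artifacts
(injection spikes, crosstalk, drift), per-vesicle loading stochasticity,
membrane saturation dynamics of the hydrophobic substrates, or
outer-reservoir depletion. Passing recovery tests therefore demonstrate
the correctness and noise robustness of the inference chain under the
stated noise model, not robustness to every systematic effect of real
plate data.

## Inference

Default signal mode is **plateau**: the mean intensity over a 60 s
window centred on the early maximum (argmax of the replicate mean
within the first 5 min). This is exactly self-consistent with the
quasi-steady-state flux balance. A **slope** mode (OLS over 4–64 s by
default) is provided because initial-rate analyses are often phrased as
slopes; the plateau mode is the default and the one validated by the
recovery studies. SEs are taken over replicate estimates.

The control subtraction scales the control's signal by the ratio of
encapsulated enzyme amounts (porin batch / control batch) before
subtracting, because the batches differ in geometry and vesicle count —
the same normalisation as plotting signals relative to polymersome
concentration. Negative porin-attributable signals are floored at zero
and flagged, so weak-transport conditions survive batch processing. The
correlation factor $F_C$ and quantum-yield factor are applied after
subtraction, on the porin-attributable signal only.

Since $H(c_S) = v_{corr}/v_{max}$, the inferred rate
$k_T = k_{cat}(N_{GLuc}/n_{tri})\,v_{corr}/v_{max}$ is linear in the
corrected signal; gauge changes that rescale intensities and $v_{max}$
jointly cancel exactly. The SEM combines the relative errors of trimer
densitometry, vesicle concentration and the quantum-yield factor in
quadrature; quadrature (not plain addition) is also used for ratios of
rates, because it reproduces the reference ratio SEMs to two decimals
(one of six is off by 0.008, attributable to rounding of the inputs).

## Problem sizes and tolerances

The recovery studies use 20 seeds, triplicates, 5% CV, the four
reference batches and the 12-point calibration series — the study's own
design — and compare medians within 10%. Noise-free end-to-end recovery
is within 2% (measured ≲ 0.5%; the residual comes from the control
subtraction approximation and optimizer truncation). Known limitations:
slope-mode inference is implemented but not calibrated against the
plateau mode; bootstrap CIs undercover at n = 3; the simulator's control
model is a two-parameter reduction of a qualitative description.
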