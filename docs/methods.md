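# Methods

This note records the models implemented in `llpsnmr`, the defaults and
their units, and the design choices made where more than one reasonable
option existed.

## Calibration and quantification

The probe chemical shift is modelled as strictly linear,
δ = δ₀ + θ_C·C + θ_T·ΔT + θ_Y·Y, with ΔT relative to a 25 °C reference.
This is the regime where the probe reports faithfully; a nonlinear
(binding-isotherm) calibration is deliberately out of scope. The
calibration fit is ordinary least squares with the full 4×4 coefficient
covariance retained; inversion to concentration propagates both the
coefficient covariance and the peak-position CI to first order (delta
method). A Monte-Carlo cross-check of the propagation is available through
the deconvolution CI engine. Negative inverted concentrations are floored
at zero for reporting but the unfloored value is retained for auditing.

Phase volumes use integral closure, V_P = (I_P/I_T)·V_O, so Σ V_P = V_O
exactly when the component areas close. The bulk observed volume defaults
to V_O = 236.8 µL; it is exposed as configuration because the observed
column length (and hence volume) is instrument- and shim-dependent. Masses
are M_P = C_P·V_P with µL→mL unit reconciliation. The conservation audit
compares Σ M_P per time against the loaded mass at a default tolerance of
5 %.

The shipped calibration coefficients are synthetic fixtures (clearly
labelled in code); their only deliberately physical property is θ_C > 0,
placing the dense phase downfield of the lean phase.

## Deconvolution

Each probe-region spectrum is fit with one or two area-parameterised
Lorentzians plus a constant baseline by bounded trust-region least squares
(FWHM ∈ [0.1, 5000] Hz, areas ≥ 0, centers inside the axis). Area
parameterisation is used because integrals are the quantitative
observable. The constant baseline absorbs residual offsets left by
automated baseline correction.

Model selection: two components are accepted only when the two-component
fit lowers the BIC by more than 10 **and** both areas exceed 2 % of the
total. The conservative threshold avoids spurious splitting of a single
pre-transition resonance; both knobs are arguments.

Confidence intervals: residual noise σ is estimated from the fit
residuals, `n_reps` (default 200, minimum 50) synthetic datasets
(model + Gaussian noise) are refit, and the 2.5/97.5 percentiles of each
parameter form the 95 % CI. Replicate components are matched to the
point-estimate components by nearest centre before taking percentiles; if
more than 20 % of replicates fail to converge the CI is flagged
unreliable. Everything is reproducible under a fixed seed.

In a kinetic series each spectrum is fit independently (identical bounds
and selection rule), but the optimiser is warm-started from the previous
time point's solution, which only affects the seed, never the criteria.

Phase labels: each centre is inverted to a concentration; lower → lean.
Coincident centres (within the overlap of their centre CIs) are broken by
width, narrower → lean, matching the phenomenology that the lean phase
gives the narrow resonance.

## Biophysical models

Water viscosity uses the Vogel-type correlation
η(T) = 2.414·10⁻⁵·10^(247.8/(T_K − 140)) Pa·s, which matches tabulated
pure-water viscosity within ~0.3 % on 0–100 °C; it is a plain function and
can be swapped out. R₂ scales as η/T (rotational correlation time,
Stokes–Einstein–Debye) and D as T/η (Stokes–Einstein); the two factors are
exact reciprocals by construction. The effective hydrodynamic radius
cancels in both scalings and is therefore never needed numerically.

Crowding-limited diffusion uses
D(φ) = D_dil·(1−φ)³/(1 + 1.5φ + 2φ² + 3φ³) with φ = C·v̄/1000 and a
protein specific volume default of 0.735 mL/g (serum albumin).

Decay fits: I(t) = I₀(1 − 2e^(−tR₁)) for inversion recovery,
I(t) = I₀e^(−tR₂) for CPMG, and
I(g) = I₀·exp(−D(γgδ_g)²(Δ − δ_g/3)) for pulsed-field-gradient diffusion,
with γ/2π = 40.078 MHz/T for ¹⁹F (any value in 40.05–40.08 MHz/T changes
the slice geometry by <1 % and the fitted D not at all, since the same
constant is used in synthesis and fitting). All three share the
Monte-Carlo CI approach.

## Spatial analysis

Slice geometry follows from the excitation physics: width = B/(γG) and
centre(offset) = offset/(γG). Defaults model a 42.4 G/cm gradient with a
16793 Hz selective pulse and 12 offsets spanning ±93404 Hz, i.e. twelve
~0.99 mm slices at −5.5…+5.5 mm; the 130.1 µL observed slice volume is
spread uniformly unless a sensitivity profile is supplied. Heights are
positive up; boundary *depth* (used for settling rates) is the negated
height so sinking gives positive rates in mm/hr.

Gradient nonlinearity is corrected by scaling each slice by
mean(reference integral)/slice reference integral — the reference fills
all slices equally, so its integral is a per-slice sensitivity measure.
The correction is idempotent.

The lean/dense boundary is defined as the depth where the dense volume
fraction crosses 50 %, linearly interpolated between adjacent slice
centres; profiles entirely above/below 50 % are reported censored, and
multiple crossings return the topmost with a flag. The two-regime settling
fit places a breakpoint at the interior sample (≥3 points per segment)
minimising the summed SSE of two independently fitted lines. Fewer than 6
points fall back to a single line, flagged.

Layer-separation onset is detected from broadening of the
concentration-insensitive reference line: baseline = median of the first
10 half-widths; onset = first time the half-width exceeds baseline by
>20 % for ≥3 consecutive samples. Threshold and persistence are exposed;
the persistence requirement rejects single-point spikes. No exceedance is
a valid result (arrested, non-settling states).

When a slice shows a single component, its calibrated concentration is
compared to the midpoint of the typical lean/dense fraction concentrations
(80/360 mg/mL) and the slice is assigned 100 % to the nearer phase.

## Kinetics

The crossover is the argmin of the dense concentration after a centred
5-sample moving average (2.5 min at 0.5 min sampling), cross-checked
against the argmax of the smoothed dense volume; disagreement beyond 3
samples is flagged rather than silently resolved. Concentration is used as
the primary signal because it is better conditioned in simulation. An
extremum at either end of the window is reported as "no crossover", which
is the expected outcome for runs still pre-crossover when observation
ends. Lag is the first time the dense volume exceeds 5 % (configurable) of
its window maximum. The growth exponent is the OLS slope of log V vs
log(t − trigger); the default window excludes the first 5 min to skip the
nucleation transient.

## Synthetic data

The generator encodes the staged phenomenology of a temperature-jump LLPS
run rather than any mechanistic nucleation model. Dense concentration
follows C_d(t) = C_min + (C_init−C_min)e^(−s/τ₁) + (C_final−C_min)(1−e^(−s/τ₂))
with s = (t − lag)₊ and τ₂ = 5τ₁; the minimum then has the closed form
s* = 1.25·τ₁·ln(5(C_init−C_min)/(C_final−C_min)), and τ₁ is solved so s*
lands on the requested crossover time. Dense volume rises as sin² to its
crossover maximum and afterwards sits on the tie-line at the current dense
concentration (lean phase pinned at its equilibrium concentration), so
compaction shrinks the volume exactly as densification proceeds; lean
concentration is always derived from exact mass conservation, and
parameter sets that would drive it negative are rejected before
generation. Arrested mode freezes the volume at its maximum while the
concentration keeps rising slowly and no settling occurs.

Presets: 40C (15 min lag, crossover 100 min, dense final 340 mg/mL),
45C (no lag, crossover 40 min, dense final 360 mg/mL), 50C-arrested
(crossover 25 min, dense final 380 mg/mL, arrested). All start from
200 mg/mL in 236.8 µL with 20 mM additive; the lean phases equilibrate at
80 mg/mL. The orderings — dense final concentration rising, dense final
volume falling with jump temperature — are emergent checks, not inputs.
Settling defaults: onset 140 min, boundary sinking at 0.154 mm/hr then
0.004 mm/hr after a 1100 min breakpoint, with a 20 % trapped lean remnant
decaying with a 400 min time constant.

Rendered spectra place the two probe Lorentzians at the calibrated shifts
with areas proportional to phase volumes and widths linear in local
concentration (5 Hz + 0.2 Hz per mg/mL, giving ~21 Hz lean / ~77 Hz dense
at the fraction concentrations), plus the reference line (3 Hz) whose
width — and every width — gains the configured inhomogeneity broadening
after settling onset. Noise is i.i.d. Gaussian in the frequency domain
(thermal noise after FT), with SNR defined as tallest *probe* peak height
over σ: the reference sits in a separate insert and is much taller than
the probe, so referencing noise to it would misstate the probe's
information content. Default synthesis resolution is 32768 points over
30 ppm (0.43 Hz/point at 470 MHz), which resolves 5 Hz features. Fixed
seeds give byte-identical spectra.

What the generator does **not** emulate: droplet-size distributions and
their exchange broadening, baseline/phase distortions, lineshape
non-Lorentzianity, radiation damping, temperature gradients during the
jump, and partial-volume excitation profiles beyond rectangular slices.
Passing the end-to-end suites therefore demonstrates correctness of the
analysis chain under the stated noise model, not robustness to every
instrumental artefact of real data.

## Numerical choices and problem sizes

Nonlinear fits use SciPy's bounded trust-region least squares with tight
tolerances (1e-14) and up to 3 jittered restarts on non-convergence;
non-convergence is always flagged, never silent. The BIC uses the
Gaussian-RSS form. OLS fits use `numpy.linalg.lstsq` with explicit
covariance; keeping the fit paths on numpy/scipy keeps the Monte-Carlo
engines fast enough that CI replication stays routine.

Test and acceptance runs use 120 min bulk windows at 0.5 min sampling
(241 spectra), a 600 min window at 2 min sampling when the phases must
reach their equilibrium concentrations, and slice series of a few dozen
time points at 4096–8192 points per spectrum — sizes chosen so the full
suite runs in well under two minutes while every recovery statement is
made at the study's stated noise levels.

## Known limitations

- The two-component model caps the description at two coexisting phases;
  >2 components and non-Lorentzian lineshapes are out of scope.
- CI propagation is first-order; strongly asymmetric posteriors (e.g. area
  of a nearly-vanished component) are better served by the Monte-Carlo
  path.
- The single-component phase assignment in slices uses a fixed
  concentration midpoint; systems whose fraction concentrations differ
  greatly from the defaults should override it.
- The boundary locator assumes a single interface; emulsified or
  multi-layer states yield a multimodality flag, not a full description.
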