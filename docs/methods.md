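# Methods

## Pressure synthesis from a volume curve

The model assumes the normalized LV elastance waveform is subject-invariant:
one dimensionless shape `E_N(u)`, `u ∈ [0, 1]`, is stretched in time and
scaled in amplitude per patient. The published digitizations of this
waveform are not distributed in a machine-readable form, so the default
shape is a double-Hill curve — the product of an activation Hill term
(`tau_rise = 0.269`, `n_rise = 1.32`) and a relaxation Hill term
(`tau_fall = 0.452`, `n_fall = 21.9`) — normalized to a unit peak and
lifted onto a diastolic baseline of 0.05. These constants give a peak near
40% of the cycle and a sharp relaxation, the canonical human morphology.
Any digitized waveform can be substituted via
`elastance_from_samples` / a two-column CSV; the curve object validates the
single-peak contract (unique maximum of 1, monotone relaxation, start at
baseline) and evaluates by linear interpolation on its own grid, so a
digitized curve is reproduced exactly at its own sample points.

**Time alignment.** "Middle of the downslope" is defined as the unique
descending-limb time where `E_N = (1 + baseline)/2`; this is computable for
any admissible waveform and reduces to the half-relaxation time for a zero
baseline. The linear map anchors normalized time 0 to the cycle start and
the mid-downslope to the minimum-volume frame; beyond the mapped support
the elastance is held at baseline. Whether cycle start should also be
anchored to the waveform start is genuinely open; the two-anchor linear map
is the simplest reading and is what is implemented.

**Amplitude scaling.** The affine form `E = a·E_N + b` is the minimal
parameterisation able to satisfy the two independent pressure constraints
(peak pressure and EDP). For a known peak frame the constraints are a
linear 2×2 system; since the argmax of `(a·E_N + b)(V − V0)` depends on
`(a, b)`, the solver iterates the system over the candidate peak frame.
This fixed point converges in 2–4 iterations for physiological inputs; a
cycle detector keeps the best candidate if the argmax oscillates between
frames, and failure to meet the peak target within 1e-6 relative raises a
scaling error rather than returning a compromised fit. The solver is
cross-checked in the tests against a coarse-to-fine 61×61 grid search over
`(a, b)` that shares no code with it.

**Fixed constants.** EDP defaults to 7 mmHg for every patient — within
reasonable limits EDP has little effect on the derived parameters — and
`V0 = 0 mL`, both configurable. The peak LV systolic pressure defaults to
the brachial systolic pressure unchanged (`method="identity"`); an affine
`c1·SBP + c0` hook is provided for calibrated brachial-to-LV transfer
expressions, whose published coefficients are not reproducible here. The
end-diastolic frame is the maximal-volume frame (earliest on ties), a
volumetric definition consistent with the model's inputs.

## Energetic parameters

Areas are computed by the shoelace formula on the implicitly closed polygon
and converted with 1 mmHg·mL = 1.33322e-4 J. Loop orientation is
normalized at construction (signed area ≥ 0), so reversed sample order is
harmless. Conventions that the source material leaves open, and the
choices made:

- **PE** is the ESPVR triangle `½·ESP·(ESV − V0)`. The area under the
  diastolic limb is neglected by default — it is second-order at
  EDP = 7 mmHg — with an optional flag that subtracts a linearized
  diastolic segment.
- **ESP** is the pressure at the maximal-elastance sample (Emax is computed
  per sample, ties to the earliest frame), not a `0.9·SBP` surrogate.
- **External power** is the cycle-mean `SW·HR/60`, not ejection-phase
  power.
- **Energy per ejected volume** is `(SW + PE)/SV` with SV the loop width
  `EDV − ESV`.
- **VE** is exactly `100·SW/(SW + PE)`; the identity is asserted per
  patient in the tests.

Degenerate inputs raise typed errors: loops with all points coincident,
`V0 ≥ ESV`, `SV ≤ 0`, zero total area, minimum volume at the first or last
frame. A loop that encloses no area returns zero stroke work with a
warning rather than a negative area.

## Synthetic cohort

The generator emulates the joint structure the analysis needs, not images:

- **Volume curves** are deterministic shape functions: half-cosine
  monotone ejection to end systole (at 35% of the cycle by default, snapped
  to the nearest frame so the minimum is attained exactly), then biphasic
  logistic filling (72% early wave, 28% atrial wave) back to EDV. 30
  frames per cycle by default, matching clinical cine temporal resolution.
- **Covariates**: age log-normal fitted to median 63 (IQR 55–70) years; EF
  a truncated normal on (5, 40)% whose *truncated* mean is solved to equal
  26% (naive truncation would bias the mean low); EDV index log-normal
  fitted to median 152 (IQR 127–178) mL/m², converted to absolute EDV with
  a fixed body-surface area of 1.9 m²; sex, etiology, hypertension and
  diabetes Bernoulli at 79/55/38/20%.
- **Unreported vitals**: heart rate 70 ± 10 bpm — consistent with a median
  stroke work of 0.86 J alongside a median external power of 1.01 J/s,
  which implies ≈70 bpm — and brachial pressure 120 ± 15 / 75 ± 10 mmHg,
  clipped to physiological ranges with pulse pressure ≥ 15 mmHg. These are
  invented defaults: per-patient blood pressure and heart rate have no
  published cohort summaries to calibrate against.
- **Outcomes**: the log-hazard is `β_VE·(−VE%) + β_NIDCM·1[nonischemic]`
  with generative defaults `exp(β_VE) = 1.04` per percentage-point VE
  decrease and `exp(β_NIDCM) = 0.42`, centered over the cohort. Event
  times are exponential (Weibull shape 1, shape configurable when a rate
  is supplied explicitly); independent exponential censoring at 0.02/yr
  stands in for noncardiovascular death, with administrative censoring at
  the 5-year horizon. The baseline rate is calibrated by root-finding on
  the closed-form expected event fraction so that a default cohort has
  ≈54% events; across seeds, n = 164 cohorts land in a 0.45–0.65 band.

What the generator does **not** emulate: segmentation error, beat-to-beat
variability, scar burden, correlations between covariates (age and
etiology are independent here, unlike in real cohorts), recurrent events,
or any real link between EF and blood pressure. Passing tests therefore
demonstrate the *pipeline's* correctness and calibration under the assumed
generative model, not clinical reproducibility on patient data.

## Survival analysis

Cox models maximize the partial likelihood with Efron tie handling (via
lifelines); Wald statistics and 95% CIs come from the observed information.
Percent-valued predictors whose decrease marks worse physiology (EF, VE)
are sign-flipped so hazard ratios read per-percentage-point decrease. The
staircase M1 (age, sex) → M2 (+ hypertension, diabetes, etiology) →
M3_V (+ EF, EDV index) / M3_PV (+ VE, SW) is fit on one common
complete-case sample so likelihood-ratio tests between nested pairs are
valid; per-model complete-case `n` is reported for standalone fits. A
Spearman screen flags pairs with |ρ| ≥ 0.8 (constant columns are flagged
with every partner since their rank correlation is undefined) and fitting
a model containing a flagged pair raises an error. Tertile cuts use the
empirical 33.3/66.7 percentiles with ties to the lower group; per-group
product-limit curves carry Greenwood-based 95% bands. Proportional-hazards
diagnostics are not gated on — lifelines' Schoenfeld-residual check remains
available to users on the fitted objects.

## Problem sizes and tolerances in the test suite

Solver contracts are checked at 1e-6 relative; analytic geometry at 1e-6;
oracle agreement (grid search, brute-force partial likelihood) at 0.1% and
1e-3 respectively. Stochastic checks use: 10,000 patients for covariate
marginals, 20,000 for hazard-ratio recovery (estimate within [1.03, 1.05]),
200 replicates of n = 164 for CI coverage (within [0.90, 0.99]), and 1,000
simulations for likelihood-ratio type-I error (within [0.03, 0.07]). These
sizes keep the full suite under a few minutes on one CPU while holding
Monte-Carlo error well inside the asserted bands.

## Known limitations

- The elastance waveform and brachial-to-LV pressure transfer are pluggable
  stand-ins for published digitizations; absolute parameter values shift
  slightly with the waveform choice (relative comparisons are stable).
- No windkessel/afterload coupling, no diastolic pressure–volume
  relationship beyond the single EDP anchor, no wave reflections.
- `V0 = 0` systematically underestimates VE when the true unloaded volume
  is positive; the bias direction is asserted as a property test across a
  grid of ventricular geometries.
- Single-beat, rest-state analysis only; no stress protocols, no
  recurrent-event or competing-risks models beyond censoring at
  noncardiovascular death.
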