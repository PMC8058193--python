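# Methods

## Scope and data model

The package operates on frame-averaged time-activity curves (TACs): per-frame
activity concentrations in kBq/cc on an acquisition schedule in minutes. The
default schedule is the 23-bin, 60-minute protocol (11×8 s, 1×12 s, 2×60 s,
1×180 s, 8×400 s). Image reconstruction, attenuation/scatter/randoms/decay
correction, and VOI delineation happen upstream; TAC values are assumed fully
decay-corrected. Arterial samples are (time, activity) pairs on the standard
12-draw timetable (10, 20, 36, 49 s; 1, 1.2, 2.2, 3.3 min; 5, 10, 30, 60 min).

## Curve algebra

Every continuous model curve is a finite sum of terms `c·uⁿ·e^(−λu)` with
`u = t − τ` (`mcifkit.expsum.ExpPolySum`). This family is closed under
running integration and convolution with a decaying exponential, so the frame
average `∫f/(tᵉ−tᵇ)` — the operator linking continuous curves to frame data —
is an exact antiderivative evaluation. The optimizers therefore never call a
quadrature. Rate collisions in convolution denominators (|λ−β| < 1e-9 1/min)
switch to the confluent `u·e^(−λu)` limit. Arbitrary callables fall back to
adaptive quadrature (absolute tolerance 1e-8) in `frame_average`; this path
is used only for cross-checks.

## Arterial input model

The seven-parameter Feng form
`C_a(t) = (A₁u − A₂ − A₃)e^(−λ₁u) + A₂e^(−λ₂u) + A₃e^(−λ₃u)`, `u = t − τ`,
is continuous with C_a(τ) = 0, and non-negative for A ≥ 0 and λ₁ > λ₂ > λ₃.
The rate ordering (which removes exponential label-permutation symmetry) is
enforced structurally by fitting λ₃ and positive increments. Default bounds
bracket rodent bolus kinetics: τ ∈ [0,1] min; λ₁ ∈ [0.5,50], λ₂ ∈ [0.05,5],
λ₃ ∈ [0,0.2] 1/min; A₁ ∈ [0,10⁴] kBq/cc/min; A₂,A₃ ∈ [0,10³] kBq/cc.

The fit is bounded least squares with 20 multi-starts (one data-driven
heuristic start plus Latin-hypercube draws, fixed seed; ties < 1e-12 broken
by smaller parameter norm). Weights default to uniform; an optional
`1/max(sample, 1% of max)` scheme up-weights the late, low-activity draws.

**Peak forcing.** When early draws miss the bolus peak, the model maximum
over the scan can be pinned to an external peak value (typically the
myocardium TAC maximum). This is a quadratic penalty — weight 10⁴ on the
relative peak error, scaled to the data sum of squares — rather than a hard
constraint, keeping the objective smooth; the weight escalates ×10 (at most
four times) until the fitted maximum is within 0.5% of the target. The
constraint pins the peak *value* only, not its time.

## Two-tissue compartment model

`dC₁/dt = K₁C_a − (k₂+k₃)C₁ + k₄C₂`, `dC₂/dt = k₃C₁ − k₄C₂`, `C_T = C₁+C₂`.
For k₄ = 0 (irreversible FDG trapping),

    C_T = [K₁k₃/(k₂+k₃)]·∫₀ᵗC_a + [K₁k₂/(k₂+k₃)]·(C_a ⊛ e^(−(k₂+k₃)t)),

with the k₂+k₃ → 0 branch collapsing to pure accumulation K₁∫C_a. For k₄ > 0
the standard two-exponential impulse response is used; the measure-zero
equal-eigenvalue point is handled by nudging k₄ by 1e-9. The net uptake rate
is `Ki = K₁k₃/(k₂+k₃)`.

Two independent numerical routes validate the closed forms: stiff LSODA
integration of the state equations (rtol 1e-10, atol 1e-12; agreement ≤ 1e-6
relative) and the Patlak graphical slope on late frames (t* = 20 min;
agreement ≤ 2% with Ki on noiseless irreversible data).

## Dual-output MCIF estimation

The 15-parameter fit minimizes `O = O₁ + O₂`: O₁ is the unweighted sum of
squared frame residuals of both model outputs; O₂ is the squared mismatch of
the blood and myocardium peak values. Peaks are maxima of *frame-wise*
quantities (model outputs and data TACs), matching the resolution of
reconstructed images; the myocardium peak is searched within the first
10 minutes on both model and data (late myocardial frames reflect trapping,
not first-pass blood). O₂ restores the influence of the few early high-value
frames that the frame-count-dominated O₁ would otherwise sacrifice.

Optimization is bounded trust-region least squares from multi-starts (default
20; Latin hypercube, fixed seed). The first start seeds the arterial
parameters from a direct seven-parameter fit to the measured blood-pool TAC
(treated as samples at frame midpoints), with kinetics and contamination at
mid-bounds. Default bounds: spillover S_mb, S_bm ∈ [0,1]; recovery r_b, r_m ∈
[0.3,1]; kinetic rates ∈ [1e-4,5] 1/min; k₄ ∈ [0,0.1] or fixed at 0 via
`fix_k4`. Identical config and seed give bit-identical results.

**Amplitude identifiability.** The model is exactly invariant under
`(C_a, C_T) → (c·C_a, c·C_T)` with all four contamination coefficients
divided by c: the data constrain the MCIF's *shape* strongly but its *scale*
only through the recovery coefficients. This is intrinsic to the model, not
an optimizer artifact. The intended use — mirrored by the recovery analyses
in the test suite — is to calibrate r_b and r_m externally (phantom scans of
known activity, scanner- and iteration-count-specific) and pass them as
`r_b_fixed`/`r_m_fixed`. With free recovery coefficients the fitted MCIF is
meaningful up to scale; its default [0.3,1] bounds are stand-ins for such a
calibration and are documented as such.

The MCIF itself is the fitted C_a(t): full-recovery and uncontaminated, not
scaled by r_b.

## Regional cerebral Ki

Each VOI is fitted with the four-parameter model (K₁, k₂, k₃, TBV; k₄ absent)
in which TBV both adds the blood signal and attenuates the tissue signal —
spillover and partial volume are coupled as TBV and 1−TBV summing to one, and
RC = 1−TBV is reported as the region's recovery coefficient. The blood term
uses the continuous input Cp(T) inside the frame integral. Bounds:
K₁,k₂,k₃ ∈ [1e-4,2] 1/min, TBV ∈ [0,0.5]; initial guess (0.1, 0.2, 0.05,
0.05); 10 multi-starts by default. Super-region TACs are volume-weighted
means of member VOI TACs (the only aggregation that reproduces whole-region
averages); super-region volume is the member sum. Reported Ki always equals
K₁k₃/(k₂+k₃) of the fitted parameters exactly.

Treating spillover and partial volume as independent regional parameters is a
documented possible extension, deliberately not implemented: with a single
regional TAC the two are not separately identifiable.

## Digital-rat phantom

`generate_truth` draws one animal's parameters from uniform ranges chosen to
resemble a fasted adult rat under anesthesia: bolus input with peak
~150–350 kBq/cc and 60-min AUC ~900–1900 kBq·min/cc (A₁ ∈ [2000,4000]
kBq/cc/min, λ₁ ∈ [3,6] 1/min, A₂ ∈ [20,40], A₃ ∈ [10,20] kBq/cc, λ₂ ∈
[0.3,0.8], λ₃ ∈ [0.01,0.02] 1/min, τ ∈ [0.1,0.4] min); myocardial K₁,k₂ ∈
[0.2,0.6], k₃ ∈ [0.05,0.15] 1/min; heart contamination S ∈ [0.1,0.3],
r_b ∈ [0.7,0.95], r_m ∈ [0.6,0.9]; cerebral K₁ ∈ [0.05,0.2], k₂ ∈ [0.1,0.4],
k₃ ∈ [0.02,0.12] 1/min, TBV ∈ [0,0.03] — implying cerebral Ki mostly in the
0.01–0.05 1/min band with recovery coefficients ≥ 0.97. Thirty-five
atlas-style VOIs are binned into four super regions (cerebellum, frontal
cortex, hippocampus, striatum). The absolute activity scale is arbitrary in
kBq/cc.

**Noise.** Frames receive independent zero-mean Gaussian noise with
`SD_i = σ₀·√(value_i/Δt_i)` — the standard count-statistics surrogate for
reconstructed-frame variance (proportional to activity, inverse to frame
duration). `sigma0_for_peak_noise` converts a desired peak-relative noise
fraction into σ₀. Arterial samples receive proportional noise (CV 3% by
default, gamma-counter repeatability). Negative noisy values are retained —
clipping would bias low-activity frames — and flagged via `allow_negative`.

What the phantom does *not* emulate: correlated noise between neighboring
regions (reconstruction covariance), time-varying spillover, motion,
dispersion between sampling site and heart, and model mismatch (the data
generator is the fitted model family). Passing recovery tests therefore
demonstrates correctness and conditioning of the estimation machinery, not
robustness to the systematic errors of real scans.

## Problem sizes and numerical choices

Study-scale analyses (the acceptance script and the heavier tests) use 3–4
optimizer starts per fit and 5 simulated animals × 20 noise replicates;
single-fit defaults keep 10–20 starts. Optimizer tolerances: ftol 1e-14,
xtol 1e-12, gtol 1e-9–1e-10. Frame membership in a peak window is by frame
midpoint; peak ties take the earliest frame. Differences in agreement
statistics are oriented computed − experimental, with sample (n−1) standard
deviations and 1.96·SD limits of agreement.

## Known limitations

- MCIF scale requires externally calibrated recovery coefficients (above).
- Under ~5% peak-relative frame noise the fitted input's 60-min AUC has a
  median error near 10%, with occasional larger excursions when the tail
  exponential trades off against myocardial spillover — a genuine
  identifiability fragility of the 15-parameter model at realistic noise.
- The regional model couples spillover and partial volume through one TBV
  parameter; regions adjacent to hot extra-cerebral structures violate this.
- No dispersion or metabolite correction (FDG requires neither in rodents on
  these time scales).
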