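# Methods

This note records the models, conventions, numerical choices and known
limitations of the `mechanostat` pipeline, in the order of its stages.

## Gating-spring stiffness model

**Model.** The antennal receiver is treated as a linear element of
asymptotic stiffness `K_inf` in parallel with one or two populations of
two-state, force-gated transducer channels. Each population j contributes a
gating compliance

    K(X) = K_inf − Σ_j N_j z_j² / (k_B T) · p_j(X)(1 − p_j(X)),
    p_j(X) = 1 / (1 + exp(−z_j (X − X0_j) / (k_B T))),

where `N_j` is the channel count, `z_j` the single-channel gating force
projected onto the receiver coordinate, and `X0_j` the displacement of
half-maximal open probability. The quasi-static force–displacement relation
`F(X) = K_inf·X − Σ_j N_j z_j [p_j(X) − p_j(0)]` is the exact antiderivative
and is used by the simulator and the force-step front-end; the identity
`K = dF/dX` is enforced in the test suite to 1e−6 relative.

**Conventions** (stated in every report's `conventions` block, since more
than one definition circulates):

- the *sensitive* population is the one with the larger z; labels are
  assigned after fitting, so they cannot switch between restarts;
- `K_GS = K_inf − K_steady` (gating springs in parallel with the
  steady-state element);
- stiffness relief `ΔK_j = N_j z_j²/(4 k_B T)` — the dip each population
  would produce alone at its half-open point; `ΔK_total = ΔK_s + ΔK_i`;
- nonlinearity extent `NL_j = ΔK_j / K_inf`;
- `k_B = 1.380649e−23 J/K`; default T = 298.15 K (25 °C), configurable —
  experiments span 18–30 °C.

**K_steady.** The parallel steady-state stiffness does not appear in K(X)
and therefore cannot be estimated from a stiffness curve alone. With
`k_steady: fixed:<value>` a measured value is used; with the default
`k_steady: fit` the model minimum over the measured displacement range (the
receiver's most compliant state) is taken as the steady-state stiffness.
This is a convention, not an estimate; reports carry it explicitly.

**Fitting.** Weighted (1/K_err²) bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) with an analytic
Jacobian. N and z are carried in log10 space because their plausible ranges
span decades; bounds are N ∈ [1, 1e7] channels, z ∈ [0.1, 1000] fN,
X0 within the data range, K_inf ∈ (0, 10·max K]. Twenty Latin-hypercube
initializations (seeded) plus data-driven starts (K_inf from the curve
maximum, dip depth/width heuristics); the lowest residual wins, ties broken
toward the smaller ΔK_total. A two-population fit whose channel count ends
at the lower bound raises a "population collapsed" warning rather than an
error. Fewer points than parameters + 4 is a hard error.

**Identifiability.** Noiseless model curves are recovered to well under 1%
(machine precision in practice). Users should know the regime where this
degrades: the sensitive-population dip depth is `ΔK_s = N_s z_s²/4k_BT` and
its width is `k_B T / z_s`; when the per-point noise approaches the dip
depth, N and z trade off along N z² ≈ const and individual channel counts
become order-of-magnitude estimates even though ΔK (the product) stays
well-determined. For the reference receiver (N_s = 100, z_s = 50 fN,
K_inf = 1 mN/m, 61 points over ±2 µm), a Fisher-information calculation
puts the best achievable standard error on N_s at several times its value
once the noise SD reaches 2% of K_inf. Condition comparisons should then be
made on ΔK and NL, which remain stable.

**Force steps.** `slope_stiffness_from_force_steps` sorts (F, X) pairs,
requires monotonicity, fits a cubic smoothing spline to F(X) (smoothing by
generalized cross-validation; data are rescaled to O(1) internally because
GCV is numerically ill-posed at SI magnitudes) and evaluates its analytic
derivative at interior points. Round-tripping simulated force steps
recovers the model stiffness within 2% away from the edges.

## FRAP logistic turnover

The symmetric four-parameter logistic is adopted because the quantity set
reported for such recoveries is exactly {τ, F_start, F_end, t½} and the
"4τ ↔ ~76%" correspondence holds only for the logistic:
F(t½ + 2τ) − F(t½ − 2τ) = (F_end − F_start)·tanh(1), i.e. 76.16% of the
total recovery regardless of parameters. Note the source material for this
analysis contains an internal inconsistency (a narrative τ ≈ 4 hr /
half-life ≈ 3 hr alongside the fitted set τ = 2.29 hr, t½ = 15.67 hr); the
package's reference parameter set is the complete fitted one, and no
attempt is made to reconcile the two.

Sampling is cross-sectional (each animal contributes one timepoint), so the
pooled (t, F) cloud is fitted; per-animal fits are not meaningful for this
design and are not offered. Initialization: F_start = min F, F_end = max F,
t½ = median t, τ = span/8, ten jittered restarts (seeded), τ optimized in
log space to keep it positive. A fit is flagged `no_recovery` when the
amplitude is below three residual RMS. Uncertainty comes from a
nonparametric bootstrap over pooled observations (default 1000 resamples,
seeded). Background subtraction is available in `normalize_intensities` but
off by default, since relative fluorescence is usually reported directly.

## Free-fluctuation analysis

**PSD.** One-sided Welch estimate: Hann window, 50% overlap, 1-s segments
by default (1 Hz resolution; configurable). Parseval (PSD integral =
variance) holds within 2% on 60-s traces.

**Oscillator fit.** S(f) = A/[(f₀² − f²)² + (f₀ f/Q)²] + B fitted in
log-power space (log residuals keep the peak from dominating), multi-start
over Q ∈ {0.8, 2, 5, 15} with all four parameters in log space. Q is
reported from the fit, not from an FWHM read-off; fits with Q ≤ 1/√2 are
flagged overdamped and have no spectral peak (best frequency undefined).
Best frequency = f₀√(1 − 1/2Q²) < f₀ always.

**Energy gain.** ⟨x²⟩ is the noise-floor-subtracted PSD integral over the
analysis band (default 100–1000 Hz), extrapolated to the full band by the
ratio of the fitted model's total to in-band integral — without this
correction a low-Q receiver's spectral tails outside the band bias the gain
negative by tens of percent. Then T_eff = K_receiver·⟨x²⟩/k_B and the gain
is reported both dimensionless (T_eff/T_bath − 1) and in joules
(k_B(T_eff − T_bath)), since both conventions are in use. Which stiffness
to use for equipartition (K_steady vs K_inf) is the user's choice; the
default configuration points at the steady-state stiffness.

**Simulator.** The thermally driven oscillator
m·ẍ + γ·ẋ + K·x = √(2γ k_B T_eff)·ξ(t), with m = K/(2πf₀)² and
γ = √(mK)/Q, is sampled by the exact-in-distribution discretization of the
linear SDE: one-step transition matrix expm(M·dt) with per-step noise
covariance derived from the stationary covariance diag(k_B T_eff/K,
k_B T_eff/m), iterated as a complex AR(1) eigenmode recursion. This is
exact at any step size (naive Euler–Maruyama inflates the stationary
variance by 1/(1 − ω₀·dt·Q), which is a 46% error at f₀ = 200 Hz, Q = 2,
dt = 1/8000 s); the sampled trace has the exact stationary variance
k_B T_eff/K, so equipartition checks are unbiased. A burn-in of 20
ring-down times removes the start transient.

## qPCR quantitation

Livak 2^−ΔΔCt with amplification efficiency fixed at 2.0 (an `efficiency`
parameter exists for assays with calibrated efficiencies). Technical
replicates are averaged per sample × gene (SD retained); ΔCt = Ct_target −
Ct_reference per sample; ΔΔCt is the treated−control difference of
condition means, or the mean of within-pair differences for paired designs
(e.g. contralateral organs of one animal). p-values are two-sided t-tests
on ΔCt values — paired t for paired designs, Student by default with a
Welch option. No multiple-testing correction is applied by default.
`rq_sd` propagates technical-replicate SDs through ΔΔCt by the delta
method: sd(rq) = ln(2)·rq·sd(ΔΔCt). Cts outside [5, 40] are flagged, never
silently dropped. Timecourses normalize each timepoint against its own
control cohort.

## Synthetic data: what it does and does not emulate

Each generator draws from the exact forward model its analysis counterpart
fits, with independent Gaussian noise: multiplicative (fractional SD 2% by
default) for stiffness curves, additive (SD 0.05) for relative
fluorescence, per-replicate Ct noise (SD 0.15 cycles, 3 technical × 5
biological replicates) for qPCR, and exact thermal/active forcing for
fluctuation traces. One master seed fans out to fixed per-generator child
streams, so adding one generator call never perturbs another's draws.

Passing recovery tests therefore demonstrates the estimators are correct
and unbiased *under the assumed models*; they say nothing about model
misspecification in real recordings — correlated drift in FRAP intensities,
non-Boltzmann adaptation in receiver mechanics, non-Lorentzian receiver
spectra, or amplification efficiencies below 2. Those effects must be
judged from fit residuals, which all fitting routines report.

Default problem sizes (61-point stiffness curves, 13 FRAP timepoints, 60-s
traces at 4 kHz, 50-seed simulation studies) were chosen to match the data
volumes such experiments produce per animal and keep a full validation run
in the minutes range on a single core.

## Known limitations

- Only steady-state gating mechanics are modelled: no force-step transients,
  adaptation motors, or receiver dynamics, and no CAP waveform analysis
  (CAP data can be tabulated but no model is fitted to it).
- K_steady from the `fit` convention is a bound, not a measurement.
- The logistic FRAP model cannot distinguish transport- from
  binding-limited recovery; it summarizes kinetics only.
- Per-neuron channel-count arithmetic and image quantitation are out of
  scope; fluorescence inputs are taken as already-extracted intensities.
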