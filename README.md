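# mechanostat

Quantitative analysis of auditory mechanotransduction in the *Drosophila*
antennal ear (Johnston's organ), for experimentalists who record antennal
mechanics, FRAP time courses, free fluctuations, or qPCR panels and want the
standard fits and statistics behind them in one tested pipeline.

The package implements four analysis stages plus matched synthetic-data
generators, so every fit can be validated by parameter recovery against
known ground truth:

1. **Gating-spring mechanics** (`mechanostat.gating_spring`). The receiver's
   slope stiffness as a function of displacement is modelled with two
   transducer-channel populations gating in a two-state Boltzmann fashion:

   K(X) = K∞ − Σⱼ Nⱼ zⱼ² / (k_B T) · pⱼ(X)(1 − pⱼ(X)),
   pⱼ(X) = 1 / (1 + exp(−zⱼ (X − X₀ⱼ)/(k_B T)))

   with channel counts Nⱼ, single-channel gating forces zⱼ and half-open
   displacements X₀ⱼ for the *sensitive* (large z) and *insensitive*
   (small z) populations. Bounded multi-start least squares recovers
   {Nⱼ, zⱼ, X₀ⱼ, K∞} per animal; derived mechanics (gating-spring stiffness
   K_GS = K∞ − K_steady, stiffness relief ΔKⱼ = Nⱼzⱼ²/4k_BT, nonlinearity
   extents NLⱼ = ΔKⱼ/K∞) and condition comparisons (ratios + t-tests)
   follow.

2. **FRAP turnover kinetics** (`mechanostat.frap`). Pooled fluorescence
   recovery after photobleaching is fitted with the four-parameter logistic
   F(t) = F_start + (F_end − F_start)/(1 + e^−(t−t½)/τ); the turnover time
   is reported as 4τ, which always covers 100·tanh(1) ≈ 76.2% of the total
   recovery. Bootstrap confidence intervals included.

3. **Free-fluctuation tuning and energy gain** (`mechanostat.fluctuation`).
   Welch periodograms of unstimulated receiver displacement are fitted with
   a damped harmonic oscillator PSD S(f) = A/[(f₀²−f²)² + (f₀f/Q)²] + B,
   giving best frequency f₀√(1 − 1/2Q²) and frequency selectivity Q. By
   equipartition, T_eff = K⟨x²⟩/k_B; the energy gain T_eff/T_bath − 1
   quantifies active amplification (0 for a passive receiver).

4. **qPCR relative quantitation** (`mechanostat.qpcr`). Livak 2^−ΔΔCt with
   RpL32 reference-gene normalization, technical-replicate averaging,
   paired/unpaired t-tests on ΔCt values, and per-timepoint controls.

## Worked example

Generate a synthetic fixture set (known ground truth: FRAP logistic
τ = 2.29 hr, qPCR fold-changes 1.85/2.22/2.48 at 0.15-cycle technical
noise), then fit it back:

```sh
mechanostat simulate --seed 7 --out fixtures
mechanostat fit-frap --input fixtures/frap.csv --bootstrap 200 --seed 7 --out frap.json
mechanostat qpcr --input fixtures/qpcr.csv --design paired --out qpcr_out
```

prints

```
tau = 2.250 hr; 4*tau = 8.998 hr
    gene  delta_delta_ct       rq    rq_sd  percent_change  p_value
inactive       -1.235358 2.354397 0.112312      135.439697 0.000051
nanchung       -1.091969 2.131647 0.098302      113.164740 0.000029
   nompC       -0.806184 1.748581 0.078557       74.858064 0.000950
```

The fitted time constant (2.25 hr from noisy data, truth 2.29 hr) says the
bleached channel pool is ~76% replaced within 4τ ≈ 9.0 hr; the qPCR table
recovers the simulated up-regulation of each channel gene (e.g. nompC
+75% fitted vs +85% simulated) with the p-values a paired t-test on
reference-normalized ΔCt values assigns.

The same stages are available as library calls (`fit_gating_spring`,
`fit_logistic_recovery`, `fit_oscillator`, `energy_gain`,
`delta_delta_ct`, ...) on in-memory arrays/DataFrames, and
`mechanostat run --manifest <csv>` dispatches a manifest-driven multi-stage
run. See `docs/methods.md` for models, conventions, and limitations.

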