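# wcfield

Noise-induced precursors of state transitions in the stochastic 1-D
Wilson–Cowan neural field.

## What this package is for

The Wilson–Cowan model describes a continuum of coupled excitatory (E) and
inhibitory (I) neural populations by their mean firing rates:

```
tau_E dE/dt = -E + S_E( w_EE ⊗ E - w_IE ⊗ I + P )
tau_I dI/dt = -I + S_I( w_EI ⊗ E - w_II ⊗ I + Q )
```

with exponential connectivity kernels `w_jk(x) = (b_jk / 2 sigma_jk)
exp(-|x|/sigma_jk)`, a logistic firing sigmoid `S_j`, and external voltage
drives P, Q.  As the drive P (or a kernel range sigma) is tuned, the
homogeneous resting state can lose stability through a saddle-node, Hopf,
Turing, or mixed-mode Turing–Hopf bifurcation.  Just *below* any of these
thresholds, small spatio-temporal white noise excites subthreshold
fluctuations whose variance grows and whose decay slows — the classic
early-warning signals of critical slowing down, relevant (for example) to
seizure anticipation.

`wcfield` provides, for computational neuroscientists studying these
phenomena:

- **model_core** (`wcfield.model`, `wcfield.params`): parameters (two shipped
  presets), sigmoid, kernels, exhaustive homogeneous steady-state solving and
  branch sweeps;
- **linear_stability** (`wcfield.stability`): the wavenumber-dependent 2×2
  Jacobian `J(q)` whose couplings are filtered by the Lorentzian
  `Λ²/(Λ²+q²)` (Λ = 1/sigma), dispersion curves `λ(q) = α(q) ± iω(q)`,
  bisection location of saddle-node and Hopf points, and peak-based
  classification of dispersion curves;
- **ou_statistics** (`wcfield.ou`): closed-form Ornstein–Uhlenbeck
  fluctuation statistics about a stable state — the stationary mode
  spectrum `G(q) = [det(A)D + (A - tr(A)I) D (A - tr(A)I)ᵀ] / [2 tr(A) det(A)]`
  with drift `A(q) = -J(q)` and diffusion
  `D = diag((c1/tau_E)², (c2/tau_I)²)`, lagged correlations
  `T(q,τ) = expm(-Aτ) G`, and point temporal autocovariance
  `C(τ) = (1/L) Σ_k T11(q_k, τ)` on the discrete rod;
- **simulator** (`wcfield.simulate`): Euler–Maruyama integration of the
  stochastic integro-differential equations on a periodic rod with
  FFT-based circular convolution;
- **fluctuation_analysis** (`wcfield.analysis`): probe-averaged temporal
  autocorrelation (tACC), snapshot-averaged spatial power spectral density
  (sPSD), decay-envelope extraction, constrained biexponential fitting
  `c1 e^{-m1 τ} + c2 e^{-m2 τ}` (m1 > m2 > 0), and precursor growth tables;
- **cli** (`wc-critical`): shell access to all stages.

Units everywhere: space um, time ms, rates 1/ms, voltages mV; wavenumbers q
are angular (rad/um) internally and reported as `q/2π` in waves/mm; temporal
frequencies as `ω/2π` in Hz.

## Worked example

Locate the two homogeneous-column bifurcations and classify the rod-column
dispersion at a supercritical Turing setting:

```python
import wcfield as wc

hm = wc.load_preset("homogeneous")
print(wc.find_saddle_node(hm, (1.5, 2.0)).critical_value)
print(wc.find_hopf(hm, (2.0, 2.4)).critical_value)

sp = wc.load_preset("space", P=2.34, sigma_EI=200.0, sigma_IE=200.0)
ss = wc.find_steady_states(sp)[-1]
print(ss.E0)
curve = wc.dispersion(sp, ss, wc.default_q_grid())
rep = wc.classify(curve)
print(rep.kind, rep.q_star_waves_per_mm)
```

prints

```
1.7892426577349767
2.197151375485778
0.08594964109740771
turing 1.6350000000000002
```

i.e. the resting branch folds at P_SN ≈ 1.78924 mV, the upper branch crosses
a Hopf point at P_HB ≈ 2.19715 mV (the branch is oscillatory-unstable below
and stable above), the rod column rests at E0 ≈ 0.0859 /ms at P = 2.34 mV,
and widening the inhibitory kernels to 200 um destabilises a spatial mode of
about 1.6 waves/mm — a Turing pattern, which a stochastic run
(`wc-critical simulate --scenario turing --P 2.34 --sigma-ei 200 --sigma-ie 200`)
develops spontaneously from noise.

The same pipeline from the shell:

```
wc-critical bifurcate --preset homogeneous --type sn --bracket 1.5 2.0
wc-critical dispersion --preset space --P 2.34 --sigma-ei 200 --sigma-ie 200 --out curve.csv
wc-critical pipeline --preset homogeneous --P 2.25 --scenario hopf --stages theory,simulate,analyze --seed 0 --out-dir hopf_run
```

The last command simulates 1 s of the subcritical Hopf-side rod, writes the
dispersion and OU-prediction tables, the raw field, and the fitted tACC
summary (`stats_fit.json` holds the variance estimate `c1+c2` and the slow
decay-rate `m2` that grow and shrink, respectively, as P approaches P_HB).

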