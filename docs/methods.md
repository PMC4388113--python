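# Methods

This note records the model conventions, numerical choices and known
limitations of `wcfield`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and parameters

The two-population Wilson–Cowan continuum is integrated in its
integro-differential form; the flux PDE (telegraph) form is used only
implicitly, through the Lorentzian factors of the linearised Jacobian.
State variables are mean firing rates E(x,t), I(x,t) in 1/ms on a 1-D rod;
couplings are exponential kernels `n_jk(x) = exp(-|x|/sigma_jk)/(2 sigma_jk)`
normalised to unit integral, scaled by strengths `b_jk` (mV·ms); the
voltage-to-rate map is the logistic sigmoid with maximum `Smax_j`, slope
`a_j` at the half-maximum threshold `theta_j`.  Subscripts are
source→target (`b_EI` couples E onto I); inhibitory terms carry explicit
minus signs, so all `b_jk ≥ 0`.

Two presets ship with the package.  Both share tau = (10, 8) ms,
b = (18, 10, 19, 0) mV·ms, Smax = (0.1, 0.15) /ms, a = 9 /mV,
theta = 2.2 mV, Q = 1.35 mV.  With these couplings the homogeneous
steady-state curve is S-shaped in the drive P, with its fold at
P_SN = 1.7892426576 mV and a Hopf point on the upper branch at
P_HB = 2.1971513755 mV (the branch is oscillatory-unstable between the two
and stable above the Hopf point); these ten-digit values are the
calibration anchors of the homogeneous column and are reproduced by the
test suite to bisection accuracy.  The presets differ in kernel ranges:
the `homogeneous` column uses sigma = (50, 110, 110, 20) um, the `space`
(cortical-rod) column sigma_EE ∈ {43, 50} um with sigma_EI = sigma_IE as
the Turing control parameter.  sigma_EE = 50 um is the default variant
because it places the supercritical Turing peak at 1.635 waves/mm
(P = 2.34 mV, sigma_EI,IE = 200 um) and the mixed-mode spatial peak at
2.60 waves/mm (P = 2 mV, sigma_EI,IE = 112 um), matching the reference
dispersion figures; the 43 um variant shifts these to 1.69 and 2.54
waves/mm and remains available as an override.

## Steady states and bifurcation location

With `b_II = 0` the I-nullcline is explicit, `I0(E0) = S_I(b_EI E0 + Q)`,
and all homogeneous states are roots of a scalar function of E0.  Roots
are captured by a 10⁴-point sign-change scan over [0, Smax_E] plus Brent
refinement (xtol 1e-14); every accepted root must satisfy both nullcline
residuals below 1e-10 (in practice < 1e-12).  With self-inhibition present
a 2-D Newton–hybrid solve from a 12×12 lattice of starts is used instead.
Branches are labelled bottom/mid/top by E0 rank, matching the S-bend
reading of the steady-state diagram.

The fold is located through the inverse branch parametrisation
`P(E0) = theta_E - ln(Smax_E/E0 - 1)/a_E - b_EE E0 + b_IE I0(E0)`, whose
stationary points (dP/dE0 = 0, available in closed form) are the
saddle-nodes.  This is algebraically equivalent to det J(0) = 0 at the
merging root but conditions the problem as a well-scaled scalar root-find,
so the fold is resolved far below the nominal 1e-10 mV tolerance without
continuation machinery.  The Hopf point is found by Brent bisection on the
trace of the q = 0 Jacobian along the tracked branch (the trace equals
twice the real part while the eigenvalue pair is complex); the
implementation verifies the pair is complex at the crossing and reports
ω/2π there.

## Dispersion and classification

A perturbation `exp(λt + iqx)` of a homogeneous state obeys a 2×2
eigenproblem in which each coupling is multiplied by
`F_jk(q) = Λ_jk²/(Λ_jk² + q²)`, the Fourier transform of the exponential
kernel; q is therefore **angular** (rad/um) everywhere internally, and
only the reporting layer converts to waves/mm (`q/2π · 1000`) and Hz
(`ω/2π · 1000`).  Eigenvalues come from the characteristic quadratic
(verified against the generic eigensolver to 1e-12 in the tests); the
dominant branch takes the larger real part, breaking ties toward larger
|Im| so the oscillation frequency survives the complex-to-real transition.
The default dispersion grid is 2001 points over q/2π ∈ [0, 5] waves/mm,
which resolves the 1.6–2.7 waves/mm peaks of interest to 0.0025 waves/mm.

Classification follows the α-peak rules: a lone q = 0 peak is
saddle-node-like (ω ≈ 0) or Hopf-like (ω ≠ 0); a lone q ≠ 0 peak is a
Turing mode; a q = 0 and a q ≠ 0 peak of comparable criticality signal a
mixed Turing–Hopf mode.  "Near zero" is set by a tolerance (default
1e-3 /ms) and "comparable" by a configurable height-ratio factor (default
10) on the peaks' distances from criticality — the literature
distinguishes strong Turing dominance from genuinely dual peaks without
quantifying the boundary, so the factor is an explicit package choice.

## Ornstein–Uhlenbeck statistics and shared normalisation

About a stable state each spatial mode is an independent 2-D OU process
with drift `A(q) = -J(q)` and diagonal diffusion
`D = diag((c1/tau_E)², (c2/tau_I)²)`.  The stationary mode covariance is
evaluated with the 2×2 closed form (equivalently the Lyapunov solution,
checked to 1e-12 against `scipy.linalg.solve_lyapunov`), and lagged
covariances use the matrix exponential via 2×2 eigendecomposition
(cross-checked against a 60-term series oracle).

Discrete-grid convention: a rod of length L with N_x cells carries modes
`q_k = 2πk/L`, k = -N_x/2 … N_x/2 - 1.  The package's temporal
autocovariance prediction is the **point** statistic

    C(τ) = (1/L) Σ_k T11(|q_k|, τ),

which is exactly the stationary autocovariance of E at one grid cell of
the matched simulation, and the empirical sPSD is scaled as
`|DFT(E - mean) · dx|² / L` so that its expectation at mode k is
`G11(q_k)` and Parseval (`Σ_k sPSD / L` = spatial variance) holds exactly
per snapshot.  With these conventions theory and simulation are compared
in absolute units with **no adjustable normalisation**; for dimensionless
ratio displays both sides may be divided by the same white-noise reference
variance `(c1/tau_E)² · tau_E / (2 dx)` (the point variance under bare
relaxation), and the arbitrary noise scale cancels.  An alternative
one-sided cycles-based integration of T11 differs from the point statistic
only by a constant factor and therefore moves no peak and changes no
ratio.

The noise amplitudes c1 = c2 = 1e-4 are package defaults chosen to keep
fluctuations deep in the linear regime (fluctuation standard deviation
~1e-4 of Smax on the default grids); only the ratios c/tau enter the
theory, and all theory-vs-simulation comparisons are scale-invariant.

## Stochastic integration

Fixed-step Euler–Maruyama.  Delta-correlated space-time white noise
discretises to independent `N(0,1)·sqrt(dt/dx)` deviates per cell and
step, scaled by c/tau.  Convolutions are circular (periodic rod) and
evaluated spectrally; the FFT path equals the direct periodic sum to
1e-12.  Kernels are sampled at cell centres on [-L/2, L/2) and
renormalised so the discrete integral is exactly one, which removes the
O(dx/sigma) quadrature bias of the sharp sigma_II = 20 um kernel and makes
a uniform field an exact fixed point of the convolution.  Fields are never
clipped to [0, Smax]: the linear theory assumes unconstrained
fluctuations, and supercritical runs saturate naturally through the
sigmoid.  Scenario defaults: saddle-node dt 0.1 ms / 10 s / L 3 mm; Hopf
dt 0.005 ms / 1 s / L 0.999 mm (666 cells); Turing dt 0.005 ms / 5 s /
L 6 mm; Turing–Hopf dt 0.005 ms / 0.5 s / L 6 mm; dx 1.5 um throughout.

## Empirical estimators

The tACC subtracts each probe's temporal mean and uses the biased
(divide-by-N) autocovariance — positive semidefinite, hence no spurious
negative tails — averaged over probes evenly spaced on the rod (defaults
300 for saddle-node runs, 100 for Hopf runs; the quantitative
theory-comparison tests use every cell).  Because sample-mean subtraction
removes part of the slow fluctuation power, quantitative comparisons are
made against the estimator's own finite-record expectation
`(1 - τ/T)(C(τ) - C̄)`, `C̄ = (2/T)∫₀ᵀ (1 - u/T) C(u) du`, which removes
the known O(τ_corr/T) systematic; raw C(τ) remains the default output.

The biexponential `c1 e^{-m1 τ} + c2 e^{-m2 τ}` is fitted to the tACC
decay envelope (zero-lag point plus |ACF| lobe maxima, linearly
interpolated; no monotone enforcement) by bounded least squares in
zero-lag units, parametrised as m1 = m2 + δ with δ > 0 so the rate
ordering holds by construction, with 8 log-spaced m2 starts and residual
tie-break.  `c1 + c2` estimates the fluctuation variance and m2 the
inverse correlation time; their growth/shrinkage along an approach
sequence is the critical-slowing summary.

Near a Hopf point the tACC side lobes ride on a monotone background
contributed by the many non-oscillatory spatial modes, which makes naive
peak-picking fragile at finite record length.  The side-lobe period is
therefore estimated from the autocorrelation of the rod-mean signal: the
spatial average projects out every nonzero-q mode, isolating the uniform
mode whose frequency ω(0) defines the lobe period.

## Study conditions used in the tests

The quantitative Hopf-side comparison uses the stable upper branch at
P = 2.25 mV (homogeneous column) on the 0.999 mm scenario rod for 1 s.
This stage was chosen so that the slowest mode's correlation time
(~190 ms) is well below the record length — a prerequisite for comparing
a single-run tACC with theory at the 15% level — while the ~45 Hz
subthreshold resonance remains clearly visible.  Approach sequences:
saddle-node P = 1.70, 1.75, 1.78 on the bottom branch (3 mm grid); Turing
sigma_EI,IE = 125, 130, 135 um at P = 2.34 mV (6 mm grid; the Turing
threshold for this drive sits near 137 um with critical mode ≈ 2.3
waves/mm).  The deterministic Turing pattern-formation check runs a
reduced 2.001 mm rod for 0.45 s, long enough for the linear-stage pattern
to emerge from 1e-4 noise at growth rate α ≈ 0.035 /ms.

## What the synthetic runs do and do not show

The simulations are the model's own dynamics, not recordings: they share
the theory's idealisations (homogeneous parameters, periodic boundaries,
white noise uncorrelated in space and time, no delays).  Agreement between
estimator and OU prediction therefore validates the implementation and the
linearisation, not the biological applicability of the model.  Real
recordings carry measurement noise, nonstationarity and unknown means;
the estimators accept user-supplied fields but the finite-record
correction assumes stationarity over the record.

## Known limitations

- Globally correlated ("spatially constant") noise, which can delay Turing
  onset, is out of scope; the noise model is fully uncorrelated.
- Wave (oscillatory Turing) instabilities cannot occur in the two-variable
  model and are not searched for.
- Two-dimensional sheets and conduction delays are not implemented.
- Very close to threshold (slowest correlation time comparable to the
  record) single-run fluctuation statistics are dominated by realisation
  noise; the package reports them but quantitative agreement with theory
  requires longer records than the default scenarios.
- The Euler scheme is first order; dt must stay well below the fastest
  relaxation time (the scenario defaults satisfy this by two orders of
  magnitude).
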