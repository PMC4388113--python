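"""Ornstein-Uhlenbeck theory of subthreshold fluctuations.

Linearising the stochastic field about a stable homogeneous state turns each
spatial Fourier mode q into an independent two-variable OU process

    d/dt [E^, I^] = -A(q) [E^, I^] + sqrt(D) xi,   A(q) = -J(q),

with diagonal diffusion D = diag((c1/tau_E)^2, (c2/tau_I)^2).  The stationary
mode covariance G(q) solves the Lyapunov equation A G + G A^T = D and has the
closed form

    G(q) = [det(A) D + (A - tr(A) I) D (A - tr(A) I)^T] / [2 tr(A) det(A)],

whose (1,1) entry is the spatial power spectral density of the E fluctuations.
The lagged covariance is T(q, tau) = expm(-A tau) G(q) for tau >= 0.

Discrete-grid conventions (shared with the simulator and the empirical
estimators in :mod:`wcfield.analysis`): on a periodic rod of length L sampled
at N_x points the modes are q_k = 2*pi*k/L for k = -N_x/2 .. N_x/2 - 1, and
the stationary variance of E at a single grid point is

    Var[E] = (1/L) * sum_k G11(|q_k|),

so the point temporal autocovariance predicted for lag tau is
C(tau) = (1/L) * sum_k T11(|q_k|, tau).  With these conventions the theory
curves are directly comparable, in absolute units, with the empirical tACC
and sPSD estimators -- no free normalisation enters.  For ratio displays both
sides may be divided by the same white-noise reference variance
(:func:`white_noise_reference_variance`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import expm

from .model import SteadyState
from .params import ModelParameters
from .stability import jacobian_q

__all__ = [
    "NoiseModel",
    "OUPrediction",
    "drift_matrix",
    "spatial_spectrum",
    "temporal_correlation",
    "temporal_acf",
    "spatial_variance_and_acf",
    "white_noise_reference_variance",
    "predict",
    "dft_wavenumbers",
]

#: default small-amplitude noise scaling (keeps fluctuations deep in the linear regime)
DEFAULT_NOISE = 1e-4


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Amplitudes c1, c2 of the spatio-temporal white noise driving E and I.

    The units of c are such that (c/tau) * sqrt(1/(dx*dt)) is a firing rate;
    only the ratios c/tau enter the theory, through the diffusion matrix.
    """

    c1: float = DEFAULT_NOISE
    c2: float = DEFAULT_NOISE

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("noise amplitudes must be non-negative")

    def diffusion_matrix(self, params: ModelParameters) -> np.ndarray:
        """D = diag((c1/tau_E)^2, (c2/tau_I)^2)."""
        return np.diag([(self.c1 / params.tau_E) ** 2, (self.c2 / params.tau_I) ** 2])


@dataclasses.dataclass(frozen=True)
class OUPrediction:
    """Closed-form fluctuation statistics at a stable homogeneous state.

    ``q_grid`` holds the non-negative angular wavenumbers of the matched
    discrete rod; ``G11`` the spatial PSD of E at those q (units (1/ms)^2 *
    um); ``tau_grid``/``C`` the point temporal autocovariance (units
    (1/ms)^2); ``spatial_variance`` equals C(0) by Parseval.
    """

    q_grid: np.ndarray
    G11: np.ndarray
    tau_grid: np.ndarray
    C: np.ndarray
    spatial_variance: float
    L_um: float
    N_x: int

    @property
    def temporal_variance(self) -> float:
        return float(self.C[0]) if self.tau_grid[0] == 0 else float(self.spatial_variance)


def drift_matrix(params: ModelParameters, ss: SteadyState, q: float) -> np.ndarray:
    """Drift matrix A(q) = -J(q); requires the mode to be stable.

    Raises ``ValueError`` naming the offending eigenvalue when any eigenvalue
    of J(q) has non-negative real part, because the stationary OU statistics
    do not exist there.
    """
    A = -jacobian_q(params, ss, q)
    ev = np.linalg.eigvals(A)
    if np.any(ev.real <= 0.0):
        bad = ev[np.argmin(ev.real)]
        raise ValueError(
            f"mode q={q} rad/um is not stable: drift eigenvalue {bad} has "
            "non-positive real part; stationary OU statistics undefined"
        )
    return A


def spatial_spectrum(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Stationary covariance G of the OU mode dx = -A x dt + sqrt(D) dW.

    Evaluates the 2x2 closed form (equivalently, solves the Lyapunov equation
    A G + G A^T = D).  Requires tr(A) > 0 and det(A) > 0 (stability).
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    tr = float(np.trace(A))
    det = float(np.linalg.det(A))
    if tr <= 0.0 or det <= 0.0:
        raise ValueError(f"drift matrix is not stable (tr={tr}, det={det})")
    M = A - tr * np.eye(2)
    return (det * D + M @ D @ M.T) / (2.0 * tr * det)


def temporal_correlation(A: np.ndarray, G: np.ndarray, tau: float) -> np.ndarray:
    """Lagged mode covariance T(q, tau) = expm(-A tau) G for tau >= 0.

    Negative lags use the stationarity symmetry T(-tau) = T(tau)^T.
    """
    if tau < 0:
        return temporal_correlation(A, G, -tau).T
    return expm(-np.asarray(A, dtype=float) * tau) @ np.asarray(G, dtype=float)


def dft_wavenumbers(L_um: float, N_x: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative angular wavenumbers q_k = 2*pi*k/L of an N_x-point rod.

    Returns ``(q, mult)`` where ``mult`` counts how many of the N_x DFT modes
    alias onto each non-negative q (2 for interior modes, 1 for q=0 and, when
    N_x is even, for the Nyquist mode), so that sums over the full mode set
    can be taken over the one-sided grid.
    """
    k = np.arange(0, N_x // 2 + 1)
    q = 2.0 * np.pi * k / L_um
    mult = np.full(len(k), 2.0)
    mult[0] = 1.0
    if N_x % 2 == 0:
        mult[-1] = 1.0
    else:
        mult[-1] = 2.0
    return q, mult


def _mode_matrices(params, ss, noise, q):
    D = noise.diffusion_matrix(params)
    out = []
    for qi in q:
        A = drift_matrix(params, ss, float(qi))
        out.append((A, spatial_spectrum(A, D)))
    return out


def temporal_acf(
    params: ModelParameters,
    ss: SteadyState,
    noise: NoiseModel,
    L_um: float,
    N_x: int,
    tau_grid,
    normalize: bool = False,
) -> np.ndarray:
    """Theoretical point temporal autocovariance C(tau) on the matched rod.

    Sums T11(q_k, tau) over the discrete DFT mode set and divides by L, which
    is exactly the stationary autocovariance of E at a single grid point of
    the simulated field.  All modes must be stable; unstable ones are listed
    in the raised error.  With ``normalize=True`` the curve is returned as a
    ratio to the white-noise reference variance.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    q, mult = dft_wavenumbers(L_um, N_x)
    unstable = []
    mats = []
    for qi in q:
        try:
            A = drift_matrix(params, ss, float(qi))
        except ValueError:
            unstable.append(float(qi))
            continue
        mats.append((A, spatial_spectrum(A, noise.diffusion_matrix(params)), None))
    if unstable:
        raise ValueError(
            f"{len(unstable)} modes are unstable (alpha >= 0) at q = "
            f"{unstable[:5]}{'...' if len(unstable) > 5 else ''} rad/um; "
            "OU statistics undefined"
        )
    C = np.zeros_like(tau_grid)
    for (A, G, _), m in zip(mats, mult):
        # eigendecompose once per mode: expm(-A tau) via 2x2 diagonalisation
        w, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        # T11(tau) = [V exp(-w tau) V^-1 G]_{11}
        VG = Vinv @ G
        coeff = V[0, :] * VG[:, 0]  # sum_j V[0,j] e^{-w_j tau} (V^-1 G)[j,0]
        C += m * np.real(coeff[None, :] @ np.exp(-np.outer(tau_grid, w)).T).ravel()
    C /= L_um
    if normalize:
        C = C / white_noise_reference_variance(params, noise, L_um / N_x)
    return C


def finite_record_expectation(
    C_long: np.ndarray,
    lags_long: np.ndarray,
    T_ms: float,
    lags_out: np.ndarray,
) -> np.ndarray:
    """Expected value of the mean-subtracted biased tACC estimator.

    Subtracting each probe's sample mean over a record of length T removes
    part of the slow fluctuation power, so the estimator's expectation is
    not C(tau) but approximately

        (1 - tau/T) * (C(tau) - C_bar),
        C_bar = (2/T) * int_0^T (1 - u/T) C(u) du.

    ``C_long`` must cover lags out to T for the C_bar integral.  Comparing a
    measured tACC against this curve removes the known O(tau_corr / T)
    finite-record bias from the theory-vs-simulation comparison.
    """
    lags_long = np.asarray(lags_long, dtype=float)
    C_long = np.asarray(C_long, dtype=float)
    lags_out = np.asarray(lags_out, dtype=float)
    if lags_long[-1] < 0.99 * T_ms:
        raise ValueError("C_long must extend to the record length T for the bias integral")
    sel = lags_long <= T_ms
    w = 1.0 - lags_long[sel] / T_ms
    c_bar = 2.0 * np.trapezoid(w * C_long[sel], lags_long[sel]) / T_ms
    C_out = np.interp(lags_out, lags_long, C_long)
    return (1.0 - lags_out / T_ms) * (C_out - c_bar)


def spatial_variance_and_acf(prediction: OUPrediction) -> tuple[float, np.ndarray, np.ndarray]:
    """Spatial variance and spatial autocorrelation from the predicted G11.

    The variance is the discrete mode sum (1/L) * sum_k G11(|q_k|); the
    spatial ACF is the inverse DFT of the two-sided spectrum, returned on the
    rod's offset grid (um) as ``(variance, x_offsets, acf)``.  The ACF is real
    and even and equals the variance at zero offset.
    """
    N = prediction.N_x
    L = prediction.L_um
    # reassemble the two-sided spectrum in numpy DFT order
    G_two = np.zeros(N)
    half = N // 2
    G_two[: half + 1] = prediction.G11[: half + 1]
    for k in range(1, (N - 1) // 2 + 1):
        G_two[N - k] = prediction.G11[k]
    acf = np.fft.ifft(G_two).real * N / L
    variance = float(acf[0])
    x = np.fft.fftfreq(N, d=1.0 / N) * (L / N)
    order = np.argsort(x)
    return variance, x[order], acf[order]


def white_noise_reference_variance(
    params: ModelParameters, noise: NoiseModel, dx_um: float
) -> float:
    """Point variance of the noise pushed through bare relaxation only.

    Replacing J(q) by the uncoupled diag(-1/tau_E, -1/tau_I) for every mode
    gives Var_ref = (c1/tau_E)^2 * tau_E / (2 dx).  Dividing both theory and
    simulation by this same number yields the dimensionless ratio form used
    for precursor-growth displays, independent of the arbitrary noise scale.
    """
    d1 = (noise.c1 / params.tau_E) ** 2
    return d1 * params.tau_E / (2.0 * dx_um)


def predict(
    params: ModelParameters,
    ss: SteadyState,
    noise: NoiseModel,
    L_um: float,
    N_x: int,
    tau_grid,
) -> OUPrediction:
    """Full OU prediction (sPSD, tACC, variances) for a matched discrete rod."""
    q, _ = dft_wavenumbers(L_um, N_x)
    D = noise.diffusion_matrix(params)
    G11 = np.empty(len(q))
    for i, qi in enumerate(q):
        A = drift_matrix(params, ss, float(qi))
        G11[i] = spatial_spectrum(A, D)[0, 0]
    tau_grid = np.asarray(tau_grid, dtype=float)
    C = temporal_acf(params, ss, noise, L_um, N_x, tau_grid)
    _, mult = dft_wavenumbers(L_um, N_x)
    variance = float(np.sum(mult * G11) / L_um)
    return OUPrediction(
        q_grid=q,
        G11=G11,
        tau_grid=tau_grid,
        C=C,
        spatial_variance=variance,
        L_um=L_um,
        N_x=N_x,
    )
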