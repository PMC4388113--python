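"""Linear stability of the homogeneous state: dispersion curves and bifurcations.

A perturbation ~ exp(lambda*t + i*q*x) of the homogeneous fixed point obeys a
2x2 eigenproblem in which each coupling is filtered by the Lorentzian Fourier
transform of its exponential kernel, F_jk(q) = Lambda_jk^2 / (Lambda_jk^2 + q^2)
with Lambda_jk = 1/sigma_jk.  The wavenumber q is ANGULAR (rad/um) throughout;
reported spatial frequencies use q/2pi converted to waves/mm, temporal
frequencies use omega/2pi converted to Hz.

The dominant eigenvalue lambda(q) = alpha(q) + i*omega(q) organises the
bifurcation zoo: alpha crossing zero at q = 0 with omega = 0 signals a
saddle-node, with omega != 0 a Hopf; a crossing at q != 0 a Turing pattern;
simultaneous q = 0 and q != 0 peaks a mixed-mode Turing-Hopf.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .model import (
    SteadyState,
    _jacobian_q0,
    _residuals,
    find_steady_states,
    sigmoid,
    sigmoid_deriv,
    steady_state_inputs,
)
from .params import ModelParameters

__all__ = [
    "DispersionCurve",
    "BifurcationReport",
    "jacobian_q",
    "dispersion",
    "find_saddle_node",
    "find_hopf",
    "classify",
    "waves_per_mm",
    "q_from_waves_per_mm",
    "omega_to_hz",
]

#: tolerance on the steady-state residual before a Jacobian is evaluated
SS_RESIDUAL_TOL = 1e-9
#: bisection tolerance on bifurcation control-parameter values (mV)
P_TOL = 1e-10


def waves_per_mm(q) -> np.ndarray | float:
    """Convert angular wavenumber (rad/um) to spatial frequency q/2pi in waves/mm."""
    return np.asarray(q) / (2.0 * np.pi) * 1000.0


def q_from_waves_per_mm(f):
    """Inverse of :func:`waves_per_mm`."""
    return np.asarray(f) * 2.0 * np.pi / 1000.0


def omega_to_hz(omega) -> np.ndarray | float:
    """Convert angular temporal frequency (rad/ms) to Hz."""
    return np.asarray(omega) / (2.0 * np.pi) * 1000.0


@dataclasses.dataclass(frozen=True)
class DispersionCurve:
    """Dominant eigenvalue of the linearised field over a wavenumber grid.

    ``alpha`` is the larger real part of the two eigenvalues at each q
    (damping rate, 1/ms); ``omega`` is |Im| of that dominant eigenvalue
    (rad/ms).  ``eigenvalues`` holds both branches, shape (len(q_grid), 2).
    """

    q_grid: np.ndarray
    alpha: np.ndarray
    omega: np.ndarray
    eigenvalues: np.ndarray
    steady_state: SteadyState

    @property
    def q_waves_per_mm(self) -> np.ndarray:
        return waves_per_mm(self.q_grid)


@dataclasses.dataclass(frozen=True)
class BifurcationReport:
    """Location and classification of an instability.

    ``kind`` is one of ``saddle_node``, ``hopf``, ``turing``, ``turing_hopf``
    or ``none``.  ``critical_value`` is the control-parameter value (mV for P
    sweeps) when the report comes from a bisection, or None for dispersion
    classification.  ``q_star`` is the critical angular wavenumber (rad/um,
    0 for purely temporal instabilities) and ``frequency_hz`` the temporal
    frequency omega/2pi at q = 0 where applicable.
    """

    kind: str
    critical_value: float | None = None
    q_star: float | None = None
    frequency_hz: float | None = None

    @property
    def q_star_waves_per_mm(self) -> float | None:
        return None if self.q_star is None else float(waves_per_mm(self.q_star))


def _lorentzian_factors(params: ModelParameters, q):
    q2 = np.asarray(q, dtype=float) ** 2
    out = {}
    for pair in ("EE", "EI", "IE", "II"):
        lam2 = params.Lambda(pair) ** 2
        out[pair] = lam2 / (lam2 + q2)
    return out


def _check_on_fixed_point(params: ModelParameters, ss: SteadyState) -> None:
    res = _residuals(ss.E0, ss.I0, params)
    if max(abs(res[0]), abs(res[1])) > SS_RESIDUAL_TOL:
        raise ValueError(
            f"(E0, I0)=({ss.E0}, {ss.I0}) is not a fixed point of these "
            f"parameters (nullcline residuals {res}); refusing to linearise"
        )


def jacobian_q(params: ModelParameters, ss: SteadyState, q: float) -> np.ndarray:
    """The 2x2 wavenumber-dependent Jacobian J(q) at a fixed point (1/ms).

    At q = 0 all Lorentzian factors are 1 and J(0) is the Jacobian of the
    homogeneous two-variable system; as q -> inf the couplings vanish and
    J -> diag(-1/tau_E, -1/tau_I).
    """
    _check_on_fixed_point(params, ss)
    v_E, v_I = steady_state_inputs(ss.E0, ss.I0, params)
    dSE = sigmoid_deriv(v_E, "E", params)
    dSI = sigmoid_deriv(v_I, "I", params)
    F = _lorentzian_factors(params, q)
    return np.array(
        [
            [
                (-1.0 + dSE * params.b_EE * F["EE"]) / params.tau_E,
                -dSE * params.b_IE * F["IE"] / params.tau_E,
            ],
            [
                dSI * params.b_EI * F["EI"] / params.tau_I,
                (-1.0 - dSI * params.b_II * F["II"]) / params.tau_I,
            ],
        ]
    )


def _eig2x2(J11, J12, J21, J22):
    """Eigenvalues of a real 2x2 via the characteristic quadratic (vectorised)."""
    tr = J11 + J22
    det = J11 * J22 - J12 * J21
    disc = np.asarray(tr * tr - 4.0 * det, dtype=complex)
    root = np.sqrt(disc)
    return (tr + root) / 2.0, (tr - root) / 2.0


def dispersion(params: ModelParameters, ss: SteadyState, q_grid) -> DispersionCurve:
    """Evaluate the dispersion relation lambda(q) over a grid of wavenumbers.

    The dominant branch is the eigenvalue with the larger real part; on ties
    (the complex-to-real transition) the member with larger |Im| is kept so
    the oscillation frequency is not spuriously dropped.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid < 0) or np.any(np.diff(q_grid) < 0):
        raise ValueError("q_grid must be non-negative and sorted")
    _check_on_fixed_point(params, ss)
    v_E, v_I = steady_state_inputs(ss.E0, ss.I0, params)
    dSE = sigmoid_deriv(v_E, "E", params)
    dSI = sigmoid_deriv(v_I, "I", params)
    F = _lorentzian_factors(params, q_grid)
    J11 = (-1.0 + dSE * params.b_EE * F["EE"]) / params.tau_E
    J12 = -dSE * params.b_IE * F["IE"] / params.tau_E
    J21 = dSI * params.b_EI * F["EI"] / params.tau_I
    J22 = (-1.0 - dSI * params.b_II * F["II"]) / params.tau_I + np.zeros_like(q_grid)
    lam1, lam2 = _eig2x2(J11, J12, J21, J22)
    eigs = np.stack([lam1, lam2], axis=-1)
    # dominant: larger real part; tie -> larger |Im|
    first = (lam1.real > lam2.real) | (
        (lam1.real == lam2.real) & (np.abs(lam1.imag) >= np.abs(lam2.imag))
    )
    dom = np.where(first, lam1, lam2)
    return DispersionCurve(
        q_grid=q_grid,
        alpha=dom.real,
        omega=np.abs(dom.imag),
        eigenvalues=eigs,
        steady_state=ss,
    )


def default_q_grid(max_waves_per_mm: float = 5.0, n: int = 2001) -> np.ndarray:
    """Angular q grid whose q/2pi axis spans [0, max_waves_per_mm] waves/mm."""
    return q_from_waves_per_mm(np.linspace(0.0, max_waves_per_mm, n))


# ---------------------------------------------------------------------------
# bifurcation location in the control parameter P
# ---------------------------------------------------------------------------

def _fold_parametrisation(params: ModelParameters):
    """For b_II = 0 the steady-state curve can be inverted: P as a function of E0.

    P(E0) = theta_E - ln(Smax_E/E0 - 1)/a_E - b_EE*E0 + b_IE*S_I(b_EI*E0 + Q).
    Folds of the S-bend are the stationary points of P(E0); dP/dE0 is
    available in closed form, so the fold is a scalar root-find, accurate to
    machine precision.
    """

    def P_of_E0(E0):
        I0 = sigmoid(params.b_EI * E0 + params.Q, "I", params)
        return (
            params.theta_E
            - np.log(params.Smax_E / E0 - 1.0) / params.a_E
            - params.b_EE * E0
            + params.b_IE * I0
        )

    def dP_dE0(E0):
        dI = sigmoid_deriv(params.b_EI * E0 + params.Q, "I", params) * params.b_EI
        return (
            params.Smax_E / (params.a_E * E0 * (params.Smax_E - E0))
            - params.b_EE
            + params.b_IE * dI
        )

    return P_of_E0, dP_dE0


def find_saddle_node(params: ModelParameters, P_bracket: tuple[float, float]) -> BifurcationReport:
    """Locate the fold (saddle-node) of the steady-state curve inside a P bracket.

    With ``b_II = 0`` the fold is found as a stationary point of the inverse
    branch parametrisation P(E0) (equivalent to det J(0) = 0 at the merging
    root, but conditioned like a scalar root-find); otherwise a bisection on
    the root count is used.  The result is refined well below ``P_TOL``.
    """
    Pa, Pb = sorted(P_bracket)
    if params.b_II == 0.0:
        P_of_E0, dP_dE0 = _fold_parametrisation(params)
        E = np.linspace(1e-9, params.Smax_E - 1e-9, 40_000)
        d = dP_dE0(E)
        folds = []
        for i in np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0):
            e_star = optimize.brentq(dP_dE0, E[i], E[i + 1], xtol=1e-16, rtol=8.9e-16)
            P_star = float(P_of_E0(e_star))
            if Pa <= P_star <= Pb:
                folds.append((P_star, e_star))
        if not folds:
            raise ValueError(f"no fold found for P in [{Pa}, {Pb}] mV")
        P_star, _ = min(folds, key=lambda t: t[0])
    else:
        P_star = _fold_by_root_count(params, Pa, Pb)
    return BifurcationReport(kind="saddle_node", critical_value=P_star, q_star=0.0, frequency_hz=0.0)


def _root_count(params: ModelParameters, P: float) -> int:
    return len(find_steady_states(params.replace(P=P)))


def _fold_by_root_count(params: ModelParameters, Pa: float, Pb: float) -> float:
    na, nb = _root_count(params, Pa), _root_count(params, Pb)
    if na == nb:
        raise ValueError(
            f"bracket [{Pa}, {Pb}] does not span a fold (root count {na} at both ends)"
        )
    while Pb - Pa > P_TOL:
        Pm = 0.5 * (Pa + Pb)
        if _root_count(params, Pm) == na:
            Pa = Pm
        else:
            Pb = Pm
    return 0.5 * (Pa + Pb)


def find_hopf(
    params: ModelParameters,
    P_bracket: tuple[float, float],
    branch: str = "top",
) -> BifurcationReport:
    """Locate the Hopf point where Re(lambda) of the q=0 complex pair crosses zero.

    Tracks the requested branch (by E0 rank) over P, bisecting on the trace
    of the q=0 Jacobian — which equals twice the real part while the pair is
    complex.  Raises if the pair is real at the crossing (that would be a
    fold, not a Hopf) or if no sign change spans the bracket.
    """
    Pa, Pb = sorted(P_bracket)

    def tracked_state(P: float) -> SteadyState:
        states = find_steady_states(params.replace(P=P))
        if branch == "top":
            return states[-1]
        if branch == "bottom":
            return states[0]
        for st in states:
            if st.branch == branch:
                return st
        raise ValueError(f"branch {branch!r} not present at P={P}")

    def trace_q0(P: float) -> float:
        ss = tracked_state(P)
        J = _jacobian_q0(ss.E0, ss.I0, params.replace(P=P))
        return float(J[0, 0] + J[1, 1])

    fa, fb = trace_q0(Pa), trace_q0(Pb)
    if fa * fb > 0:
        raise ValueError(
            f"Re(lambda(q=0)) does not change sign on [{Pa}, {Pb}] "
            f"(trace {fa:.3g} .. {fb:.3g}); no Hopf in bracket"
        )
    P_star = optimize.brentq(trace_q0, Pa, Pb, xtol=P_TOL, rtol=8.9e-16)
    ss = tracked_state(P_star)
    J = _jacobian_q0(ss.E0, ss.I0, params.replace(P=P_star))
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    if tr * tr - 4.0 * det >= 0.0:
        raise ValueError(
            f"eigenvalue pair is real at the trace zero (P={P_star}); this is "
            "a fold-type degeneracy, not a Hopf bifurcation"
        )
    omega = float(np.sqrt(4.0 * det - tr * tr) / 2.0)
    return BifurcationReport(
        kind="hopf",
        critical_value=float(P_star),
        q_star=0.0,
        frequency_hz=float(omega_to_hz(omega)),
    )


# ---------------------------------------------------------------------------
# dispersion-curve classification
# ---------------------------------------------------------------------------

def _local_maxima(alpha: np.ndarray) -> list[int]:
    """Indices of local maxima of alpha, including the endpoints when they dominate."""
    idx = [
        i
        for i in range(1, len(alpha) - 1)
        if alpha[i] >= alpha[i - 1] and alpha[i] >= alpha[i + 1]
    ]
    if len(alpha) >= 2 and alpha[0] > alpha[1]:
        idx.insert(0, 0)
    if len(alpha) >= 2 and alpha[-1] > alpha[-2]:
        idx.append(len(alpha) - 1)
    return idx


def classify(
    curve: DispersionCurve,
    tol: float = 1e-3,
    comparable_factor: float = 10.0,
) -> BifurcationReport:
    """Classify the instability implied by a dispersion curve's alpha peaks.

    Peaks of alpha(q) within ``tol`` (1/ms) of zero or above are treated as
    (near-)critical.  A lone q = 0 peak is saddle-node-like when omega(0) is
    (near) zero and Hopf-like otherwise; a lone q != 0 peak is a Turing mode;
    a q = 0 peak and a q != 0 peak whose alpha distances from zero are within
    ``comparable_factor`` of one another signal a mixed-mode Turing-Hopf.
    Returns kind "none" when every peak is below -tol.
    """
    peaks = _local_maxima(curve.alpha)
    crit = [i for i in peaks if curve.alpha[i] >= -tol]
    if not crit:
        return BifurcationReport(kind="none")
    zero_peaks = [i for i in crit if curve.q_grid[i] == 0.0 or i == 0]
    nonzero_peaks = [i for i in crit if i not in zero_peaks]
    f0 = float(omega_to_hz(curve.omega[0]))
    if zero_peaks and nonzero_peaks:
        iz, inz = zero_peaks[0], max(nonzero_peaks, key=lambda i: curve.alpha[i])
        # compare proximity to criticality rather than raw (negative) heights
        hz_, hnz = curve.alpha[iz], curve.alpha[inz]
        comparable = max(abs(hz_), abs(hnz)) <= comparable_factor * max(min(abs(hz_), abs(hnz)), tol) or (
            hz_ >= -tol and hnz >= -tol
        )
        if comparable:
            return BifurcationReport(
                kind="turing_hopf",
                q_star=float(curve.q_grid[inz]),
                frequency_hz=f0,
            )
        if hnz > hz_:
            return BifurcationReport(kind="turing", q_star=float(curve.q_grid[inz]))
        zero_peaks, nonzero_peaks = [iz], []
    if nonzero_peaks:
        inz = max(nonzero_peaks, key=lambda i: curve.alpha[i])
        return BifurcationReport(kind="turing", q_star=float(curve.q_grid[inz]))
    if curve.omega[0] > tol:
        return BifurcationReport(kind="hopf", q_star=0.0, frequency_hz=f0)
    return BifurcationReport(kind="saddle_node", q_star=0.0, frequency_hz=0.0)
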