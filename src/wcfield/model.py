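"""Core Wilson-Cowan continuum model: sigmoid, kernels, steady states.

The two-population model couples excitatory (E) and inhibitory (I) mean
firing rates through exponentially decaying connectivity kernels and a
logistic firing-rate sigmoid.  In the spatially homogeneous limit the
convolutions collapse and the steady states are the intersections of the
two nullclines

    E0 = S_E(b_EE*E0 - b_IE*I0 + P)
    I0 = S_I(b_EI*E0 - b_II*I0 + Q)

which this module locates exhaustively.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ModelParameters, _check_pair, _check_pop

__all__ = [
    "SteadyState",
    "sigmoid",
    "sigmoid_deriv",
    "kernel",
    "steady_state_inputs",
    "find_steady_states",
    "steady_state_branch",
]

#: residual tolerance below which a candidate root is accepted as a steady state
ROOT_TOL = 1e-12
#: number of scan points for the dense sign-change sweep over [0, Smax_E]
SCAN_POINTS = 10_000


@dataclasses.dataclass(frozen=True)
class SteadyState:
    """A homogeneous fixed point (E0, I0) of the deterministic model.

    ``eigenvalues`` are the two eigenvalues of the q=0 Jacobian (1/ms);
    ``stable`` is True when both real parts are negative.  ``branch`` labels
    the fixed point by its E0 rank at the given P (bottom/mid/top) and is
    None when only a single root exists.
    """

    E0: float
    I0: float
    P: float
    eigenvalues: tuple[complex, complex]
    stable: bool
    branch: str | None = None

    @property
    def alpha0(self) -> float:
        """Dominant damping rate at q=0 (1/ms)."""
        return max(ev.real for ev in self.eigenvalues)


def sigmoid(v, pop: str, params: ModelParameters):
    """Logistic firing-rate function S_j(v) = Smax_j / (1 + exp(-a_j (v - theta_j))).

    Parameters
    ----------
    v : float or array
        Membrane voltage (mV); must be finite.
    pop : {"E", "I"}
        Which population's sigmoid to evaluate.

    Returns
    -------
    Firing rate in 1/ms, strictly inside (0, Smax_j).
    """
    _check_pop(pop)
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input voltage must be finite")
    a = getattr(params, f"a_{pop}")
    theta = getattr(params, f"theta_{pop}")
    smax = getattr(params, f"Smax_{pop}")
    with np.errstate(over="ignore"):  # exp overflow -> inf -> S -> 0, correct limit
        out = smax / (1.0 + np.exp(-a * (v - theta)))
    return float(out) if out.ndim == 0 else out


def sigmoid_deriv(v, pop: str, params: ModelParameters):
    """Slope dS_j/dv (rate per mV), via the logistic identity S' = a*S*(1 - S/Smax)."""
    _check_pop(pop)
    a = getattr(params, f"a_{pop}")
    smax = getattr(params, f"Smax_{pop}")
    s = sigmoid(v, pop, params)
    return a * s * (1.0 - s / smax)


def kernel(x, pair: str, params: ModelParameters, weighted: bool = False):
    """Exponential connectivity kernel.

    ``weighted=False`` returns the normalized density
    n_jk(x) = exp(-|x|/sigma_jk) / (2 sigma_jk)  (units 1/um), which
    integrates to one; ``weighted=True`` returns w_jk = b_jk * n_jk
    (mV*ms/um), which integrates to b_jk.
    """
    _check_pair(pair)
    x = np.asarray(x, dtype=float)
    sig = params.sigma(pair)
    n = np.exp(-np.abs(x) / sig) / (2.0 * sig)
    if weighted:
        n = params.b(pair) * n
    return float(n) if n.ndim == 0 else n


def steady_state_inputs(E0: float, I0: float, params: ModelParameters) -> tuple[float, float]:
    """Voltage arguments (v_E, v_I) entering the two sigmoids at a fixed point."""
    v_E = params.b_EE * E0 - params.b_IE * I0 + params.P
    v_I = params.b_EI * E0 - params.b_II * I0 + params.Q
    return v_E, v_I


def _residuals(E0: float, I0: float, params: ModelParameters) -> tuple[float, float]:
    v_E, v_I = steady_state_inputs(E0, I0, params)
    return E0 - sigmoid(v_E, "E", params), I0 - sigmoid(v_I, "I", params)


def _jacobian_q0(E0: float, I0: float, params: ModelParameters) -> np.ndarray:
    """Jacobian of the homogeneous (q=0) system at (E0, I0)."""
    v_E, v_I = steady_state_inputs(E0, I0, params)
    dSE = sigmoid_deriv(v_E, "E", params)
    dSI = sigmoid_deriv(v_I, "I", params)
    return np.array(
        [
            [(-1.0 + dSE * params.b_EE) / params.tau_E, -dSE * params.b_IE / params.tau_E],
            [dSI * params.b_EI / params.tau_I, (-1.0 - dSI * params.b_II) / params.tau_I],
        ]
    )


def _make_state(E0: float, I0: float, params: ModelParameters, branch: str | None) -> SteadyState:
    ev = np.linalg.eigvals(_jacobian_q0(E0, I0, params))
    # order by real part descending so eigenvalues[0] is dominant
    ev = sorted((complex(e) for e in ev), key=lambda z: (-z.real, -abs(z.imag)))
    return SteadyState(
        E0=E0,
        I0=I0,
        P=params.P,
        eigenvalues=(ev[0], ev[1]),
        stable=all(e.real < 0 for e in ev),
        branch=branch,
    )


def _scalar_root_fn(params: ModelParameters):
    """With b_II = 0 the I-nullcline is explicit: I0(E0) = S_I(b_EI E0 + Q).

    Returns f(E0) = E0 - S_E(b_EE E0 - b_IE I0(E0) + P), whose roots on
    [0, Smax_E] are the homogeneous steady states.
    """

    def f(E0):
        I0 = sigmoid(params.b_EI * E0 + params.Q, "I", params)
        return E0 - sigmoid(params.b_EE * E0 - params.b_IE * I0 + params.P, "E", params)

    return f


def find_steady_states(params: ModelParameters, n_scan: int = SCAN_POINTS) -> list[SteadyState]:
    """Locate all homogeneous steady states at the parameters' current P.

    With ``b_II = 0`` (the usual configuration) the problem reduces to a
    scalar root-find, handled by a dense sign-change scan over [0, Smax_E]
    followed by bracketed Brent refinement.  With self-inhibition present
    the 2-D nullcline system is solved from a lattice of starting points
    and deduplicated.  Roots are returned sorted by E0 and labelled
    bottom/mid/top when three coexist.
    """
    roots: list[float] = []
    if params.b_II == 0.0:
        f = _scalar_root_fn(params)
        grid = np.linspace(0.0, params.Smax_E, n_scan)
        vals = f(grid)
        sign = np.sign(vals)
        for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
            r = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
            roots.append(r)
        for i in np.flatnonzero(vals == 0.0):
            roots.append(float(grid[i]))
        pairs = []
        for E0 in sorted(roots):
            I0 = sigmoid(params.b_EI * E0 + params.Q, "I", params)
            pairs.append((E0, I0))
    else:
        pairs = _find_steady_states_2d(params)

    if not pairs:
        raise RuntimeError(
            f"no steady state found at P={params.P} mV; the dense scan over "
            f"[0, Smax_E] with {n_scan} points detected no sign change"
        )
    for E0, I0 in pairs:
        res = _residuals(E0, I0, params)
        if max(abs(res[0]), abs(res[1])) > 1e-10:
            raise RuntimeError(f"root refinement did not converge: residuals {res}")

    labels: list[str | None]
    if len(pairs) == 3:
        labels = ["bottom", "mid", "top"]
    elif len(pairs) == 1:
        labels = [None]
    else:
        labels = [f"branch{i}" for i in range(len(pairs))]
    return [_make_state(E0, I0, params, lab) for (E0, I0), lab in zip(pairs, labels)]


def _find_steady_states_2d(params: ModelParameters, n_starts: int = 12) -> list[tuple[float, float]]:
    def sys(z):
        return _residuals(z[0], z[1], params)

    found: list[tuple[float, float]] = []
    for e0 in np.linspace(0.0, params.Smax_E, n_starts):
        for i0 in np.linspace(0.0, params.Smax_I, n_starts):
            sol = optimize.root(sys, [e0, i0], method="hybr", tol=1e-14)
            if not sol.success:
                continue
            E0, I0 = sol.x
            if not (-1e-9 <= E0 <= params.Smax_E + 1e-9):
                continue
            if all(abs(E0 - e) > 1e-8 for e, _ in found):
                found.append((float(np.clip(E0, 0, params.Smax_E)), float(I0)))
    return sorted(found)


def steady_state_branch(params: ModelParameters, P_grid) -> pd.DataFrame:
    """Sweep P and tabulate every steady state (the S-shaped branch diagram).

    Returns a DataFrame with columns P, E0, I0, branch, stable and the real
    and imaginary parts of both q=0 eigenvalues, sorted by (P, E0).
    """
    P_grid = np.asarray(P_grid, dtype=float)
    if not np.all(np.isfinite(P_grid)):
        raise ValueError("P_grid must be finite")
    if np.any(np.diff(P_grid) < 0):
        raise ValueError("P_grid must be sorted ascending")
    rows = []
    for P in P_grid:
        for ss in find_steady_states(params.replace(P=float(P))):
            rows.append(
                {
                    "P": P,
                    "E0": ss.E0,
                    "I0": ss.I0,
                    "branch": ss.branch if ss.branch else "single",
                    "stable": ss.stable,
                    "re_lambda1": ss.eigenvalues[0].real,
                    "im_lambda1": ss.eigenvalues[0].imag,
                    "re_lambda2": ss.eigenvalues[1].real,
                    "im_lambda2": ss.eigenvalues[1].imag,
                }
            )
    return pd.DataFrame(rows)
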