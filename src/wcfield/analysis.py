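"""Empirical precursor statistics from simulated (or recorded) fields.

The estimators here share the discrete-grid conventions of :mod:`wcfield.ou`:
the probe-averaged temporal autocovariance (tACC) estimates the OU point
autocovariance C(tau) and the snapshot-averaged spatial periodogram (sPSD)
estimates the mode spectrum G11(q), both in absolute units, so theory and
simulation can be overlaid with no adjustable normalisation.

Critical-slowing summaries follow the standard recipe: the tACC decay
envelope is fitted with a biexponential c1*exp(-m1 tau) + c2*exp(-m2 tau),
m1 > m2 > 0; the amplitude sum estimates the fluctuation variance and the
slow rate m2 is the inverse correlation time, both of which diverge on
approach to a bifurcation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import SpaceTimeField

__all__ = [
    "AcfFit",
    "empirical_tacc",
    "empirical_spsd",
    "envelope",
    "fit_biexponential",
    "precursor_summary",
]


@dataclasses.dataclass(frozen=True)
class AcfFit:
    """Biexponential fit c1*exp(-m1 tau) + c2*exp(-m2 tau) with m1 > m2 > 0."""

    c1: float
    c2: float
    m1: float
    m2: float
    residual: float

    @property
    def variance(self) -> float:
        """Zero-lag value of the fitted curve, estimating the fluctuation variance."""
        return self.c1 + self.c2

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        return self.c1 * np.exp(-self.m1 * tau) + self.c2 * np.exp(-self.m2 * tau)


def _biased_autocov(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased (divide-by-N) autocovariance of a 1-D series via the FFT.

    The biased estimator is positive semidefinite, which avoids spurious
    negative tails at long lags.
    """
    x = x - x.mean()
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n_lags] / n
    return acov


def empirical_tacc(
    field: SpaceTimeField,
    n_probes: int = 300,
    max_lag_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probe-averaged temporal autocovariance of the E field.

    ``n_probes`` probes are taken evenly spaced along the rod; each probe's
    temporal mean is removed and its biased autocovariance computed, then
    averaged across probes.  Returns ``(lags_ms, mean_acf, per_probe)`` with
    ``per_probe`` of shape (n_probes, n_lags).
    """
    E = field.E
    n_t, n_x = E.shape
    if n_probes > n_x:
        raise ValueError(f"n_probes={n_probes} exceeds grid size {n_x}")
    dt = field.dt_recorded
    n_lags = int(round(max_lag_ms / dt)) + 1
    if n_lags >= n_t:
        raise ValueError(
            f"max_lag {max_lag_ms} ms needs more than the {n_t} recorded steps"
        )
    cols = np.linspace(0, n_x, n_probes, endpoint=False).astype(int)
    if np.ptp(E[:, cols]) == 0.0:
        raise ValueError("field is constant; autocovariance undefined")
    per_probe = np.empty((n_probes, n_lags))
    for i, c in enumerate(cols):
        per_probe[i] = _biased_autocov(E[:, c], n_lags)
    lags = np.arange(n_lags) * dt
    return lags, per_probe.mean(axis=0), per_probe


def empirical_spsd(
    field: SpaceTimeField,
    n_snapshots: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Snapshot-averaged spatial periodogram of the E field.

    Each selected snapshot is mean-subtracted, periodogrammed as
    |DFT(E) * dx|^2 / L, and averaged.  With this scaling the expectation of
    the periodogram at mode q_k is the OU spectrum G11(q_k) and the Parseval
    identity sum(sPSD) / L = spatial variance holds exactly per snapshot.
    Returns ``(q_rad_per_um, mean_psd)`` on the one-sided mode grid.
    """
    E = field.E
    n_t, n_x = E.shape
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    n_snapshots = min(n_snapshots, n_t)
    rows = np.linspace(0, n_t - 1, n_snapshots).astype(int)
    dx = field.config.dx
    L = field.config.L_um
    snaps = E[rows] - E[rows].mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(snaps, axis=1) * dx) ** 2 / L
    q = 2.0 * np.pi * np.arange(spec.shape[1]) / L
    return q, spec.mean(axis=0)


def uniform_mode_acf(
    field: SpaceTimeField, max_lag_ms: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal autocovariance of the spatially uniform (q = 0) mode.

    Averaging the rod at each instant projects out every nonzero spatial
    mode, isolating the global mode whose oscillation sets the Hopf
    side-lobe period of the tACC.  Returns ``(lags_ms, acf)``.
    """
    m = field.E.mean(axis=1)
    dt = field.dt_recorded
    n_lags = int(round(max_lag_ms / dt)) + 1
    if n_lags >= len(m):
        raise ValueError("record shorter than the requested maximum lag")
    return np.arange(n_lags) * dt, _biased_autocov(m, n_lags)


def lobe_period(lags: np.ndarray, acf: np.ndarray) -> float:
    """Oscillation period of an ACF from the mean spacing of its lobe peaks.

    Uses the zero-lag point plus every interior local maximum of the ACF;
    raises if no interior lobe exists (non-oscillatory ACF).
    """
    acf = np.asarray(acf, dtype=float)
    lags = np.asarray(lags, dtype=float)
    pk = [0] + [
        i for i in range(1, len(acf) - 1) if acf[i] >= acf[i - 1] and acf[i] >= acf[i + 1]
    ]
    if len(pk) < 2:
        raise ValueError("ACF has no side lobes; oscillation period undefined")
    return float(np.diff(lags[pk]).mean())


def envelope(acf: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Decay envelope of an (possibly oscillatory) autocorrelation function.

    The envelope passes through the zero-lag point and the local maxima of
    |ACF|, linearly interpolated back onto the lag grid.  For a monotone
    ACF with no interior lobes the envelope is |ACF| itself.  No
    monotone-decreasing enforcement is applied; the biexponential fit
    absorbs residual non-monotonicity.
    """
    acf = np.asarray(acf, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if not np.all(np.isfinite(acf)):
        raise ValueError("ACF contains non-finite values")
    a = np.abs(acf)
    peaks = [0] + [
        i for i in range(1, len(a) - 1) if a[i] >= a[i - 1] and a[i] >= a[i + 1]
    ]
    if len(peaks) < 2:
        return a
    return np.interp(lags, lags[peaks], a[peaks])


def fit_biexponential(
    lags: np.ndarray,
    acf_envelope: np.ndarray,
    n_starts: int = 8,
) -> AcfFit:
    """Nonlinear least-squares biexponential fit with multi-start initialisation.

    Rates are parametrised as m1 = m2 + delta with delta > 0 so the ordering
    m1 > m2 > 0 holds by construction.  ``n_starts`` slow-rate initial
    guesses are log-spaced over the observable decay band; the best residual
    wins.  Raises ``RuntimeError`` (carrying the best residual) if no start
    converges.
    """
    lags = np.asarray(lags, dtype=float)
    y = np.asarray(acf_envelope, dtype=float)
    if len(lags) < 8:
        raise ValueError("need at least 8 envelope points to fit 4 parameters")
    if y[0] <= 0:
        raise ValueError("envelope must be positive at zero lag")
    span = lags[-1] - lags[0]
    scale = y[0]
    yn = y / scale  # fit in zero-lag units so the optimiser sees O(1) residuals

    def model(theta, tau):
        c1, c2, m2, delta = theta
        return c1 * np.exp(-(m2 + delta) * tau) + c2 * np.exp(-m2 * tau)

    best = None
    m2_grid = np.logspace(np.log10(0.05 / span), np.log10(5.0 / span), n_starts)
    for m2_0 in m2_grid:
        theta0 = [0.5, 0.5, m2_0, 10.0 * m2_0]
        try:
            res = optimize.least_squares(
                lambda th: model(th, lags) - yn,
                theta0,
                bounds=([0.0, 0.0, 1e-12, 1e-12], [np.inf] * 4),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("biexponential fit failed from every start")
    c1, c2, m2, delta = best.x
    return AcfFit(
        c1=float(c1 * scale),
        c2=float(c2 * scale),
        m1=float(m2 + delta),
        m2=float(m2),
        residual=float(scale * np.sqrt(2.0 * best.cost / len(lags))),
    )


def precursor_summary(stages: list[dict]) -> pd.DataFrame:
    """Tabulate critical-slowing indicators across an approach sequence.

    Each stage is a mapping with a ``label`` plus any of: ``fit`` (an
    :class:`AcfFit`), ``spsd`` as a ``(q, psd)`` pair, or pre-computed
    scalars.  The output table holds, per stage, the fitted variance
    (c1 + c2), the slow decay rate m2, and the sPSD peak height and its
    location -- the quantities whose monotone growth (variance, peak) and
    shrinkage (m2) flag an approaching bifurcation.
    """
    if len(stages) < 2:
        raise ValueError("need at least two approach stages to summarise growth")
    rows = []
    for st in stages:
        row = {"label": st.get("label")}
        fit = st.get("fit")
        if fit is not None:
            row["variance"] = fit.variance
            row["m2"] = fit.m2
        if "spsd" in st:
            q, psd = st["spsd"]
            q = np.asarray(q, dtype=float)
            psd = np.asarray(psd, dtype=float)
            i = int(np.argmax(psd))
            row["spsd_peak"] = float(psd[i])
            row["spsd_peak_q"] = float(q[i])
        for key in ("variance", "m2", "spsd_peak", "spsd_peak_q"):
            if key in st:
                row[key] = st[key]
        rows.append(row)
    return pd.DataFrame(rows)
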