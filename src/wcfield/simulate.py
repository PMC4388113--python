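"""Euler-Maruyama integration of the stochastic integro-differential field.

The rod of length L is sampled at N_x points with periodic boundaries; the
four kernel convolutions are evaluated spectrally (circular convolution via
the FFT, mathematically identical to the direct periodic sum).  The noise is
delta-correlated in space and time, so each Euler step adds independent
N(0, 1) * sqrt(dt/dx) * c/tau deviates per grid cell and population.

Kernels are sampled at the grid offsets on [-L/2, L/2) and renormalised so
their discrete integral is exactly one, removing the O(dx/sigma) quadrature
bias that the sharp sigma_II = 20 um kernel would otherwise incur.  Fields
are never clipped to [0, Smax]: the linearised theory assumes unconstrained
fluctuations, and supercritical runs explore the sigmoid saturation naturally.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import find_steady_states, sigmoid
from .params import ModelParameters

__all__ = [
    "SimulationConfig",
    "SpaceTimeField",
    "SCENARIOS",
    "scenario_config",
    "sample_kernel",
    "circular_convolve",
    "EulerSimulator",
    "run",
]

#: per-scenario grid and duration defaults: (dt ms, duration s, L mm)
SCENARIOS: dict[str, dict[str, float]] = {
    "sn": {"dt": 0.1, "duration_s": 10.0, "L_mm": 3.0},
    "hopf": {"dt": 0.005, "duration_s": 1.0, "L_mm": 0.999},
    "turing": {"dt": 0.005, "duration_s": 5.0, "L_mm": 6.0},
    "turing_hopf": {"dt": 0.005, "duration_s": 0.5, "L_mm": 6.0},
}


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Grid, duration, noise and bookkeeping for one stochastic run."""

    dt: float = 0.005          # time step (ms)
    dx: float = 1.5            # spatial resolution (um)
    L_mm: float = 6.0          # rod length (mm)
    duration_s: float = 1.0    # simulated time (s)
    c1: float = 1e-4           # E noise amplitude
    c2: float = 1e-4           # I noise amplitude
    seed: int = 0
    stride: int = 1            # record every `stride` steps
    init: str = "steady_state"  # or "custom"
    scenario: str | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0 or self.duration_s <= 0:
            raise ValueError("dt, dx and duration must be positive")
        if self.stride < 1:
            raise ValueError("record stride must be >= 1")
        n = self.L_um / self.dx
        if abs(n - round(n)) > 1e-9 * max(n, 1.0):
            raise ValueError(
                f"L/dx = {n} is not an integer number of grid cells"
            )

    @property
    def L_um(self) -> float:
        return self.L_mm * 1000.0

    @property
    def N_x(self) -> int:
        return int(round(self.L_um / self.dx))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.dt))


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Default configuration for one of the four bifurcation scenarios.

    Scenario rows follow the standard protocol: saddle-node runs use a
    coarse dt = 0.1 ms over 10 s on a 3 mm rod; the oscillatory and pattern
    scenarios use dt = 0.005 ms on shorter horizons.  dx = 1.5 um always.
    (The Hopf rod is 0.999 mm: 666 cells of 1.5 um.)
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kw: dict = dict(SCENARIOS[name], scenario=name)
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclasses.dataclass(frozen=True)
class SpaceTimeField:
    """Recorded E(x,t), I(x,t) on the periodic grid, with axis metadata."""

    E: np.ndarray          # (n_recorded, N_x), 1/ms
    I: np.ndarray
    x_um: np.ndarray       # (N_x,), cell centres on [-L/2, L/2)
    t_ms: np.ndarray       # (n_recorded,)
    config: SimulationConfig

    @property
    def dt_recorded(self) -> float:
        return self.config.dt * self.config.stride

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            E=self.E,
            I=self.I,
            x_um=self.x_um,
            t_ms=self.t_ms,
            config=np.array(repr(dataclasses.asdict(self.config))),
        )


def grid_offsets(N_x: int, dx: float) -> np.ndarray:
    """Cell-centre offsets on [-L/2, L/2), with x = 0 at index N_x // 2."""
    return (np.arange(N_x) - N_x // 2) * dx


def sample_kernel(params: ModelParameters, pair: str, N_x: int, dx: float) -> np.ndarray:
    """Normalised exponential kernel sampled on the rod's offset grid.

    The discrete weights are renormalised so that sum(k) * dx = 1 exactly,
    making a uniform field an exact fixed point of the convolution.
    """
    x = grid_offsets(N_x, dx)
    sig = params.sigma(pair)
    k = np.exp(-np.abs(x) / sig) / (2.0 * sig)
    return k / (k.sum() * dx)


def circular_convolve(kernel_weights: np.ndarray, field: np.ndarray, dx: float) -> np.ndarray:
    """Periodic convolution (kernel * field) * dx, centre-preserving.

    ``kernel_weights`` must be sampled on the same offset grid as the field,
    with x = 0 at index N // 2; the required half-swap (ifftshift) that moves
    the kernel origin to index 0 is applied internally, so the output at cell
    j is sum_m k(x_m) field(x_j - x_m) dx with periodic indexing.
    """
    kernel_weights = np.asarray(kernel_weights, dtype=float)
    field = np.asarray(field, dtype=float)
    if kernel_weights.shape != field.shape:
        raise ValueError(
            f"kernel and field lengths differ: {kernel_weights.shape} vs {field.shape}"
        )
    k0 = np.roll(kernel_weights, -(len(kernel_weights) // 2))  # origin to index 0
    return np.fft.irfft(
        np.fft.rfft(k0) * np.fft.rfft(field), n=len(field)
    ) * dx


class EulerSimulator:
    """Fixed-step Euler-Maruyama integrator with precomputed kernel spectra."""

    def __init__(self, params: ModelParameters, config: SimulationConfig):
        if max(params.sigma(p) for p in ("EE", "EI", "IE", "II")) * 5 > config.L_um:
            import warnings

            warnings.warn(
                "rod length is not much larger than the widest kernel "
                "(L >> sigma assumption violated)",
                stacklevel=2,
            )
        self.params = params
        self.config = config
        N, dx = config.N_x, config.dx
        self.x_um = grid_offsets(N, dx)
        self._khat = {
            pair: np.fft.rfft(np.roll(sample_kernel(params, pair, N, dx), -(N // 2))) * dx
            for pair in ("EE", "EI", "IE", "II")
        }
        self._noise_E = (config.c1 / params.tau_E) * np.sqrt(config.dt / dx)
        self._noise_I = (config.c2 / params.tau_I) * np.sqrt(config.dt / dx)

    def fluxes(self, E: np.ndarray, I: np.ndarray) -> dict[str, np.ndarray]:
        """The four convolved input fluxes phi_jk at the current instant."""
        Ehat, Ihat = np.fft.rfft(E), np.fft.rfft(I)
        n = len(E)
        return {
            "EE": np.fft.irfft(self._khat["EE"] * Ehat, n=n),
            "EI": np.fft.irfft(self._khat["EI"] * Ehat, n=n),
            "IE": np.fft.irfft(self._khat["IE"] * Ihat, n=n),
            "II": np.fft.irfft(self._khat["II"] * Ihat, n=n),
        }

    def drift(self, E: np.ndarray, I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic time-derivatives (dE/dt, dI/dt) of the field."""
        p = self.params
        n = len(E)
        Ehat = np.fft.rfft(E) if (p.b_EE or p.b_EI) else None
        Ihat = np.fft.rfft(I) if (p.b_IE or p.b_II) else None

        def flux(pair, fhat):
            return np.fft.irfft(self._khat[pair] * fhat, n=n)

        vE = np.full(n, p.P, dtype=float)
        vI = np.full(n, p.Q, dtype=float)
        if p.b_EE:
            vE += p.b_EE * flux("EE", Ehat)
        if p.b_IE:
            vE -= p.b_IE * flux("IE", Ihat)
        if p.b_EI:
            vI += p.b_EI * flux("EI", Ehat)
        if p.b_II:
            vI -= p.b_II * flux("II", Ihat)
        dE = (-E + sigmoid(vE, "E", p)) / p.tau_E
        dI = (-I + sigmoid(vI, "I", p)) / p.tau_I
        return dE, dI

    def euler_step(
        self, E: np.ndarray, I: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, np.ndarray]:
        """One Euler-Maruyama step; pass rng=None for the deterministic map."""
        dt = self.config.dt
        dE, dI = self.drift(E, I)
        E = E + dt * dE
        I = I + dt * dI
        if rng is not None and (self._noise_E or self._noise_I):
            E = E + self._noise_E * rng.standard_normal(len(E))
            I = I + self._noise_I * rng.standard_normal(len(I))
        return E, I

    def run(
        self,
        E0: np.ndarray | float | None = None,
        I0: np.ndarray | float | None = None,
    ) -> SpaceTimeField:
        """Integrate for the configured duration, recording every `stride` steps.

        By default the field starts at the homogeneous steady state (the
        stable one when several coexist; the top-most otherwise).
        """
        cfg = self.config
        N = cfg.N_x
        if E0 is None or I0 is None:
            states = find_steady_states(self.params)
            stable = [s for s in states if s.stable]
            ss = stable[-1] if stable else states[-1]
            if not ss.stable:
                import warnings

                warnings.warn(
                    "initial steady state is unstable (supercritical run)",
                    stacklevel=2,
                )
            E0 = ss.E0 if E0 is None else E0
            I0 = ss.I0 if I0 is None else I0
        E = np.broadcast_to(np.asarray(E0, dtype=float), (N,)).copy()
        I = np.broadcast_to(np.asarray(I0, dtype=float), (N,)).copy()
        rng = np.random.default_rng(cfg.seed)
        n_steps = cfg.n_steps
        n_rec = n_steps // cfg.stride + 1
        recE = np.empty((n_rec, N))
        recI = np.empty((n_rec, N))
        t_ms = np.empty(n_rec)
        recE[0], recI[0], t_ms[0] = E, I, 0.0
        j = 1
        for step in range(1, n_steps + 1):
            E, I = self.euler_step(E, I, rng)
            if step % cfg.stride == 0:
                if not (np.isfinite(E[0]) and np.isfinite(I[0])):
                    raise FloatingPointError(
                        f"field blew up (non-finite values) at step {step}"
                    )
                recE[j], recI[j], t_ms[j] = E, I, step * cfg.dt
                j += 1
        if not (np.all(np.isfinite(recE)) and np.all(np.isfinite(recI))):
            raise FloatingPointError("field blew up (non-finite values recorded)")
        return SpaceTimeField(
            E=recE[:j], I=recI[:j], x_um=self.x_um, t_ms=t_ms[:j], config=cfg
        )


def run(params: ModelParameters, config: SimulationConfig, **init) -> SpaceTimeField:
    """Convenience wrapper: build an :class:`EulerSimulator` and integrate."""
    return EulerSimulator(params, config).run(**init)
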