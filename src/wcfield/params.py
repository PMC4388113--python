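"""Model parameters for the 1-D Wilson-Cowan neural field.

Units are fixed throughout the package: space in micrometres (um), time in
milliseconds (ms), firing rates in 1/ms, voltages in mV.  Synaptic coupling
strengths ``b_jk`` carry mV*ms; kernel space constants ``sigma_jk`` carry um.
The index convention is source-to-target: ``b_EI`` couples E onto I.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from importlib import resources

__all__ = ["ModelParameters", "load_preset", "available_presets"]

_POPS = ("E", "I")
_PAIRS = ("EE", "EI", "IE", "II")


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the two-population Wilson-Cowan continuum.

    Parameters
    ----------
    tau_E, tau_I
        Relaxation time constants of the excitatory and inhibitory
        populations (ms).
    b_EE, b_EI, b_IE, b_II
        Maximum synaptic coupling strengths (mV*ms).  All are non-negative;
        inhibitory terms enter the equations with an explicit minus sign.
    sigma_EE, sigma_EI, sigma_IE, sigma_II
        Space constants of the exponential connectivity kernels (um).
    Smax_E, Smax_I
        Maximum firing rates of the sigmoids (1/ms).
    a_E, a_I
        Sigmoid slopes at threshold (1/mV).
    theta_E, theta_I
        Half-maximum firing thresholds (mV).
    P, Q
        Exogenous voltage drives to the E and I populations (mV).  P is the
        usual control parameter for bifurcation sweeps.
    """

    tau_E: float
    tau_I: float
    b_EE: float
    b_EI: float
    b_IE: float
    b_II: float
    sigma_EE: float
    sigma_EI: float
    sigma_IE: float
    sigma_II: float
    Smax_E: float
    Smax_I: float
    a_E: float
    a_I: float
    theta_E: float
    theta_I: float
    P: float
    Q: float

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "Smax_E", "Smax_I", "a_E", "a_I"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for pair in _PAIRS:
            if not getattr(self, f"sigma_{pair}") > 0:
                raise ValueError(f"sigma_{pair} must be positive")
            if getattr(self, f"b_{pair}") < 0:
                raise ValueError(
                    f"b_{pair} must be non-negative (inhibition carries its "
                    "sign explicitly in the equations)"
                )
        for name in ("theta_E", "theta_I", "P", "Q"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- convenience accessors -------------------------------------------
    def tau(self, pop: str) -> float:
        _check_pop(pop)
        return getattr(self, f"tau_{pop}")

    def b(self, pair: str) -> float:
        _check_pair(pair)
        return getattr(self, f"b_{pair}")

    def sigma(self, pair: str) -> float:
        _check_pair(pair)
        return getattr(self, f"sigma_{pair}")

    def Lambda(self, pair: str) -> float:
        """Inverse kernel length scale 1/sigma_jk (1/um)."""
        return 1.0 / self.sigma(pair)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **changes)


def _check_pop(pop: str) -> None:
    if pop not in _POPS:
        raise ValueError(f"population must be one of {_POPS}, got {pop!r}")


def _check_pair(pair: str) -> None:
    if pair not in _PAIRS:
        raise ValueError(f"pair must be one of {_PAIRS}, got {pair!r}")


def available_presets() -> list[str]:
    files = resources.files("wcfield.presets")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".toml"))


def load_preset(name: str, **overrides) -> ModelParameters:
    """Load a shipped parameter preset, optionally overriding fields.

    Two presets are shipped: ``"homogeneous"`` (space-independent reference
    column) and ``"space"`` (space-dependent cortical-rod column).  Overrides
    are validated through :class:`ModelParameters`.
    """
    path = resources.files("wcfield.presets").joinpath(f"{name}.toml")
    try:
        raw = path.read_bytes()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    data = tomllib.loads(raw.decode())
    data.update(overrides)
    return ModelParameters(**data)
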