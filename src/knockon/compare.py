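"""Model-agreement analysis and the order-of-magnitude decoherence clock.

The agreement statistic between the quantum (Spin–Boson) and classical-noise
pictures is the pointwise difference of the real parts of the coherence,

    Delta_R(t) = Re rho01_SB(t) - Re rho01_N(t),

summarized by its maximum and time-averaged absolute value over the
comparison window, plus a first-crossing "divergence time" for a configurable
threshold.  An analogous imaginary-part series is carried as a secondary
diagnostic.

Independently of the master equations, a collisional-decoherence estimate of
the decoherence time uses the thermal de Broglie wavelength of the ion:

    tau_D = DeltaX**2 / (gamma * lambda_dB**2),
    lambda_dB = hbar / sqrt(2 m k_B T),
    gamma = gamma0 * omega * nbar * r**2 / (1 + r**2),
    r = Lambda / omega,   nbar = 1 / (exp(omega / k_B T) - 1).

The position dispersion DeltaX has no canonical value for the filter, so the
estimator echoes its inputs instead of asserting a range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import constants as _const

from .core import EvolutionResult, kelvin_to_rate

__all__ = [
    "ComparisonSeries",
    "delta_R",
    "divergence_time",
    "DecoherenceEstimateParams",
    "thermal_de_broglie",
    "localization_rate",
    "decoherence_time",
    "ATOMIC_MASS_K_POTASSIUM",
]

ATOMIC_MASS_K_POTASSIUM = 39.0983 * _const.u  # kg

DEFAULT_DIVERGENCE_THRESHOLD = 0.05


@dataclass
class ComparisonSeries:
    """Aligned coherence series of two models and their difference."""

    times: np.ndarray
    r_sb: np.ndarray
    r_n: np.ndarray
    delta_r: np.ndarray
    i_sb: np.ndarray
    i_n: np.ndarray
    delta_i: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def max_abs_delta_r(self) -> float:
        return float(np.max(np.abs(self.delta_r)))

    @property
    def mean_abs_delta_r(self) -> float:
        return float(np.mean(np.abs(self.delta_r)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "R_SB": self.r_sb, "R_N": self.r_n,
             "delta_R": self.delta_r, "I_SB": self.i_sb, "I_N": self.i_n,
             "delta_I": self.delta_i}
        )

    def summary(self, threshold: float = DEFAULT_DIVERGENCE_THRESHOLD) -> dict[str, Any]:
        t_div = divergence_time(self, threshold)
        return {
            "max_abs_delta_R": self.max_abs_delta_r,
            "mean_abs_delta_R": self.mean_abs_delta_r,
            "divergence_threshold": threshold,
            "divergence_time": t_div,
            "metadata": self.metadata,
        }


def delta_R(sb: EvolutionResult, noise: EvolutionResult) -> ComparisonSeries:
    """Difference of the real parts of rho01 between two evolutions.

    Both runs must share the identical time grid; resampling is refused
    rather than silently applied.
    """
    if len(sb.times) != len(noise.times) or not np.array_equal(sb.times, noise.times):
        raise ValueError(
            "time grids differ; delta_R requires identical grids "
            "(resampling is refused, not applied)"
        )
    r_sb = sb.rho01.real
    r_n = noise.rho01.real
    i_sb = sb.rho01.imag
    i_n = noise.rho01.imag
    return ComparisonSeries(
        times=sb.times.copy(),
        r_sb=r_sb,
        r_n=r_n,
        delta_r=r_sb - r_n,
        i_sb=i_sb,
        i_n=i_n,
        delta_i=i_sb - i_n,
        metadata={"sb": dict(sb.meta), "noise": dict(noise.meta)},
    )


def divergence_time(series: ComparisonSeries, threshold: float) -> float | None:
    """First time with |Delta_R| > threshold, or None if never exceeded."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exceeded = np.abs(series.delta_r) > threshold
    if not np.any(exceeded):
        return None
    return float(series.times[int(np.argmax(exceeded))])


@dataclass(frozen=True)
class DecoherenceEstimateParams:
    """Inputs of the thermal-de-Broglie decoherence-time estimate.

    mass in kg, temperature in K, delta_x (position dispersion) in m,
    gamma0 (bare coupling rate), omega (particle frequency) and cutoff
    (environment cutoff Lambda) in 1/s.
    """

    mass: float
    temperature: float
    delta_x: float
    gamma0: float
    omega: float
    cutoff: float

    def __post_init__(self) -> None:
        for name in ("mass", "temperature", "delta_x", "gamma0", "omega", "cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def thermal_de_broglie(mass: float, temperature: float) -> float:
    """Thermal de Broglie wavelength hbar / sqrt(2 m k_B T) in metres.

    hbar is restored for dimensional output (the rate-unit convention of the
    dynamics modules does not apply to this standalone SI calculator).
    """
    if mass <= 0 or temperature <= 0:
        raise ValueError("mass and temperature must be positive")
    return _const.hbar / np.sqrt(2.0 * mass * _const.k * temperature)


def localization_rate(p: DecoherenceEstimateParams) -> float:
    """Localization (decoherence) rate gamma0 * omega * nbar * r^2/(1+r^2)."""
    thermal_rate = kelvin_to_rate(p.temperature)  # k_B T / hbar in 1/s
    x = p.omega / thermal_rate
    nbar = 1.0 / np.expm1(x)
    r = p.cutoff / p.omega
    return p.gamma0 * p.omega * nbar * r * r / (1.0 + r * r)


def decoherence_time(p: DecoherenceEstimateParams) -> float:
    """Decoherence time tau_D = DeltaX^2 / (gamma * lambda_dB^2) in seconds."""
    lam = thermal_de_broglie(p.mass, p.temperature)
    gamma = localization_rate(p)
    return p.delta_x**2 / (gamma * lam**2)
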