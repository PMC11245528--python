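"""Domain types and operator algebra for the two-configuration selectivity filter.

The KcsA selectivity filter is reduced to a two-level system: basis state
``|0>`` is the knock-on configuration with K+ ions at sites 1,3 (waters at
2,4) and ``|1>`` the configuration with K+ at sites 2,4.  The convention
``sigma_z |0> = +|0>`` is fixed here and used by every stage.  Units are
``hbar = 1`` throughout: every energy is an angular rate in 1/s, and
temperature enters only as the thermal rate ``k_B T / hbar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _const

__all__ = [
    "SIGMA_X",
    "SIGMA_Y",
    "SIGMA_Z",
    "IDENTITY",
    "pauli_operators",
    "SystemParams",
    "DensityMatrix",
    "initial_superposition",
    "system_hamiltonian",
    "EvolutionResult",
    "kelvin_to_rate",
    "rho_to_real_vector",
    "real_vector_to_rho",
    "default_time_grid",
]

SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
IDENTITY = np.eye(2, dtype=complex)


def pauli_operators() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return copies of (sigma_x, sigma_y, sigma_z) in the sigma_z eigenbasis."""
    return SIGMA_X.copy(), SIGMA_Y.copy(), SIGMA_Z.copy()


def kelvin_to_rate(temperature_kelvin: float) -> float:
    """Convert a temperature in Kelvin to the thermal rate k_B T / hbar in 1/s."""
    if temperature_kelvin <= 0:
        raise ValueError("temperature must be positive")
    return _const.k * temperature_kelvin / _const.hbar


@dataclass(frozen=True)
class SystemParams:
    """Two-level self-Hamiltonian parameters.

    Parameters
    ----------
    delta0 : float
        Tunneling (hopping) matrix element in 1/s.  Identified with the ion
        conduction rate; the physiological window is 1e6–1e8 1/s.  ``delta0 = 0``
        is allowed and gives the pure-dephasing limit.
    omega0 : float
        Asymmetry energy between the two knock-on configurations, in 1/s.
        The configurations are treated as near-degenerate; 0 by default.
    """

    delta0: float
    omega0: float = 0.0

    def __post_init__(self) -> None:
        if self.delta0 < 0:
            raise ValueError("delta0 must be non-negative")
        if self.omega0 < 0:
            raise ValueError("omega0 must be non-negative")


def system_hamiltonian(params: SystemParams) -> np.ndarray:
    """Self-Hamiltonian H_s = (omega0/2) sigma_z - (delta0/2) sigma_x."""
    return 0.5 * params.omega0 * SIGMA_Z - 0.5 * params.delta0 * SIGMA_X


_HERM_TOL = 1e-10


class DensityMatrix:
    """A 2x2 density matrix with monitored (not enforced) physicality.

    Hermiticity and unit trace are validated at construction to ``1e-10``;
    positivity is reported through :meth:`min_eigenvalue` but never enforced,
    since the Born–Markov stages are not of Lindblad form and may transiently
    violate it.
    """

    __slots__ = ("_m",)

    def __init__(self, matrix: np.ndarray, *, check: bool = True) -> None:
        m = np.asarray(matrix, dtype=complex)
        if m.shape != (2, 2):
            raise ValueError("density matrix must be 2x2")
        if check:
            if abs(m[0, 0].imag) > _HERM_TOL or abs(m[1, 1].imag) > _HERM_TOL:
                raise ValueError("diagonal elements must be real")
            if abs(m[1, 0] - np.conj(m[0, 1])) > _HERM_TOL:
                raise ValueError("matrix is not Hermitian")
            if abs(m[0, 0] + m[1, 1] - 1.0) > _HERM_TOL:
                raise ValueError("trace must be 1 at construction")
        self._m = m

    @classmethod
    def from_state_vector(cls, psi: Sequence[complex]) -> "DensityMatrix":
        v = np.asarray(psi, dtype=complex).reshape(2)
        v = v / np.linalg.norm(v)
        return cls(np.outer(v, np.conj(v)))

    @property
    def matrix(self) -> np.ndarray:
        return self._m.copy()

    @property
    def rho00(self) -> complex:
        return self._m[0, 0]

    @property
    def rho01(self) -> complex:
        return self._m[0, 1]

    @property
    def rho10(self) -> complex:
        return self._m[1, 0]

    @property
    def rho11(self) -> complex:
        return self._m[1, 1]

    def trace(self) -> complex:
        return self._m[0, 0] + self._m[1, 1]

    def purity(self) -> float:
        return float(np.real(np.trace(self._m @ self._m)))

    def hermiticity_defect(self) -> float:
        return float(np.max(np.abs(self._m - self._m.conj().T)))

    def min_eigenvalue(self) -> float:
        return float(np.min(np.linalg.eigvalsh(0.5 * (self._m + self._m.conj().T))))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DensityMatrix({self._m!r})"


def initial_superposition() -> DensityMatrix:
    """The equal superposition (|0> + |1>)/sqrt(2) as a density matrix.

    This is the pure state used as the initial condition of every run:
    rho = [[1/2, 1/2], [1/2, 1/2]].
    """
    return DensityMatrix(0.5 * np.ones((2, 2), dtype=complex))


# --- real-vector packing (solvers work on 8 real components; Hermiticity is
# --- never assumed, because neither master-equation form guarantees it) ------

def rho_to_real_vector(rho: np.ndarray) -> np.ndarray:
    """Pack a (possibly non-Hermitian) 2x2 complex matrix into 8 reals."""
    r = np.asarray(rho, dtype=complex).reshape(4)
    return np.concatenate([r.real, r.imag])


def real_vector_to_rho(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rho_to_real_vector`."""
    y = np.asarray(y, dtype=float)
    return (y[:4] + 1j * y[4:]).reshape(2, 2)


@dataclass
class EvolutionResult:
    """A density-matrix time series with solver diagnostics.

    Attributes
    ----------
    times : ndarray, shape (n,)
        Strictly increasing times in seconds, starting at the initial time.
    states : ndarray, shape (n, 2, 2)
        Complex density matrices; ``states[0]`` is the supplied initial state.
    trace_drift : float
        ``max_t |Tr rho(t) - 1|`` over the run.
    purity : ndarray, shape (n,)
        ``Re Tr rho(t)^2`` per saved step.
    meta : dict
        Solver name, tolerances, equation form, seeds, and any diagnostics.
    """

    times: np.ndarray
    states: np.ndarray
    trace_drift: float
    purity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=complex)
        if self.states.shape != (len(self.times), 2, 2):
            raise ValueError("states must have shape (len(times), 2, 2)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def rho01(self) -> np.ndarray:
        return self.states[:, 0, 1]

    @property
    def hermiticity_defect(self) -> float:
        return float(
            np.max(np.abs(self.states - np.conj(np.swapaxes(self.states, 1, 2))))
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the CSV schema: t, re/im of all elements, trace, purity."""
        s = self.states
        return pd.DataFrame(
            {
                "t": self.times,
                "re_rho00": s[:, 0, 0].real,
                "im_rho00": s[:, 0, 0].imag,
                "re_rho01": s[:, 0, 1].real,
                "im_rho01": s[:, 0, 1].imag,
                "re_rho10": s[:, 1, 0].real,
                "im_rho10": s[:, 1, 0].imag,
                "re_rho11": s[:, 1, 1].real,
                "im_rho11": s[:, 1, 1].imag,
                "trace_re": (s[:, 0, 0] + s[:, 1, 1]).real,
                "purity": self.purity,
            }
        )


def evolution_diagnostics(times: np.ndarray, states: np.ndarray, meta: dict) -> EvolutionResult:
    """Assemble an :class:`EvolutionResult`, computing trace drift and purity."""
    states = np.asarray(states, dtype=complex)
    traces = states[:, 0, 0] + states[:, 1, 1]
    purity = np.real(np.einsum("tij,tji->t", states, states))
    drift = float(np.max(np.abs(traces - 1.0)))
    return EvolutionResult(times=times, states=states, trace_drift=drift, purity=purity, meta=meta)


def default_time_grid(delta0: float, gamma: float, n_points: int = 2001) -> np.ndarray:
    """Default window t in [0, 10/min(delta0, 2*gamma)] with n_points samples.

    Covers several coherence oscillations and decay times for every printed
    parameter set; rates that are zero are ignored in the minimum.
    """
    rates = [r for r in (delta0, 2.0 * gamma) if r > 0]
    if not rates:
        raise ValueError("at least one of delta0, gamma must be positive")
    return np.linspace(0.0, 10.0 / min(rates), n_points)
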