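"""Averaged master equations for classical stochastic-Hamiltonian dephasing.

The noise enters the Hamiltonian as H(t) = H0 + z(t) * sigma_z with
H0 = (omega0/2) sigma_z - (delta0/2) sigma_x and z(t) a real, zero-mean
process.  Two ensemble-level equations are integrated:

* **White Gaussian noise**, correlation C(t) = alpha * delta(t)
  (flat power spectrum S(omega) = alpha / 2 pi; recorded here for reference,
  never used computationally).  The averaged equation is exact:

      drho/dt = -i [H0, rho] - (alpha/2) [sigma_z, [sigma_z, rho]],

  i.e. off-diagonal decay at 2*alpha, trace and Hermiticity conserved.

* **Ornstein–Uhlenbeck noise**, C(t) = (alpha'/2 tau) exp(-|t|/tau).  The
  normative equation is the second-order memory-kernel master equation

      drho/dt = -i [H0, rho] - [sigma_z, K(t)],
      K(t) = int_0^t ds C(t-s) U0(t-s) [sigma_z, rho(s)] U0(t-s)^dag,

  solved by two independent discretizations with the same contract:
  (a) direct history quadrature (trapezoid over the stored rho(s), fixed-step
  Heun) and (b) an auxiliary-operator ODE, exact for the single-exponential
  OU kernel:

      dK/dt = C(0) [sigma_z, rho] - K/tau - i [H0, K].

The published component form of the OU equation is asymmetric (an
unevaluated time integral in one line) and cannot be made
Hermiticity-consistent as printed; it is treated as a non-normative symbolic
instance and the memory-kernel operator equation above is what is solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm as _expm  # noqa: F401  (oracle route in tests)

from .core import (
    SIGMA_X,
    SIGMA_Z,
    DensityMatrix,
    EvolutionResult,
    SystemParams,
    evolution_diagnostics,
    real_vector_to_rho,
    rho_to_real_vector,
)

__all__ = [
    "NoiseSpec",
    "white_rhs",
    "free_propagator",
    "ou_memory_rhs",
    "evolve_noise",
]

RTOL = 1e-10
ATOL = 1e-12


@dataclass(frozen=True)
class NoiseSpec:
    """Classical-noise process descriptor.

    ``white``: C(t) = alpha * delta(t), strength ``alpha`` in 1/s.
    ``ou``: C(t) = (alpha'/2 tau) exp(-|t|/tau) with strength ``alpha_prime``
    in 1/s and correlation time ``tau_corr`` in s.
    """

    kind: str
    alpha: float | None = None
    alpha_prime: float | None = None
    tau_corr: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "white":
            if self.alpha is None or self.alpha < 0:
                raise ValueError("white noise requires alpha >= 0")
        elif self.kind == "ou":
            if self.alpha_prime is None or self.alpha_prime < 0:
                raise ValueError("ou noise requires alpha_prime >= 0")
            if self.tau_corr is None or self.tau_corr <= 0:
                raise ValueError("ou noise requires tau_corr > 0")
        else:
            raise ValueError(f"kind must be 'white' or 'ou', got {self.kind!r}")

    @property
    def stationary_variance(self) -> float:
        """C(0) = alpha' / (2 tau) for the OU process."""
        if self.kind != "ou":
            raise ValueError("stationary variance is defined for OU noise only")
        return self.alpha_prime / (2.0 * self.tau_corr)


def white_rhs(
    t: float, rho: np.ndarray, system: SystemParams, noise: NoiseSpec
) -> np.ndarray:
    """Exact averaged generator for white Gaussian dephasing noise."""
    if noise.kind != "white":
        raise ValueError("white_rhs requires white noise")
    h0 = 0.5 * system.omega0 * SIGMA_Z - 0.5 * system.delta0 * SIGMA_X
    comm = h0 @ rho - rho @ h0
    sz_rho = SIGMA_Z @ rho - rho @ SIGMA_Z
    double = SIGMA_Z @ sz_rho - sz_rho @ SIGMA_Z
    return -1j * comm - 0.5 * noise.alpha * double


def _su2_step(bx: float, bz: float) -> np.ndarray:
    """exp(-i (bx sigma_x + bz sigma_z)) via the closed SU(2) formula."""
    angle = np.hypot(bx, bz)
    if angle == 0.0:
        return np.eye(2, dtype=complex)
    c, s = np.cos(angle), np.sin(angle) / angle
    return np.array(
        [[c - 1j * s * bz, -1j * s * bx], [-1j * s * bx, c + 1j * s * bz]],
        dtype=complex,
    )


def free_propagator(dt: float, system: SystemParams) -> np.ndarray:
    """U0(dt) = exp(-i H0 dt), unitary to machine precision."""
    return _su2_step(-0.5 * system.delta0 * dt, 0.5 * system.omega0 * dt)


def ou_memory_rhs(
    t: float,
    rho: np.ndarray,
    kernel_op: np.ndarray,
    system: SystemParams,
    noise: NoiseSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled right-hand sides (drho/dt, dK/dt) of the auxiliary-operator route.

    Valid because the OU kernel is a single exponential: differentiating the
    memory integral K(t) gives a local ODE with decay 1/tau and the free
    rotation of the integrand.
    """
    if noise.kind != "ou":
        raise ValueError("ou_memory_rhs requires OU noise")
    h0 = 0.5 * system.omega0 * SIGMA_Z - 0.5 * system.delta0 * SIGMA_X
    drho = (
        -1j * (h0 @ rho - rho @ h0)
        - (SIGMA_Z @ kernel_op - kernel_op @ SIGMA_Z)
    )
    dk = (
        noise.stationary_variance * (SIGMA_Z @ rho - rho @ SIGMA_Z)
        - kernel_op / noise.tau_corr
        - 1j * (h0 @ kernel_op - kernel_op @ h0)
    )
    return drho, dk


def _evolve_white(rho0: DensityMatrix, system, noise, grid) -> EvolutionResult:
    def rhs(t, y):
        return rho_to_real_vector(white_rhs(t, real_vector_to_rho(y), system, noise))

    sol = solve_ivp(rhs, (grid[0], grid[-1]), rho_to_real_vector(rho0.matrix),
                    method="LSODA", t_eval=grid, rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise RuntimeError(f"white-noise integration failed: {sol.message}")
    states = np.array([real_vector_to_rho(y) for y in sol.y.T])
    meta = {"model": "classical_noise", "noise": "white", "alpha": noise.alpha,
            "solver": "LSODA", "rtol": RTOL, "atol": ATOL, "nfev": int(sol.nfev),
            "omega0": system.omega0, "delta0": system.delta0}
    return evolution_diagnostics(grid, states, meta)


def _evolve_ou_aux(rho0: DensityMatrix, system, noise, grid) -> EvolutionResult:
    def rhs(t, y):
        rho = real_vector_to_rho(y[:8])
        k = real_vector_to_rho(y[8:])
        drho, dk = ou_memory_rhs(t, rho, k, system, noise)
        return np.concatenate([rho_to_real_vector(drho), rho_to_real_vector(dk)])

    y0 = np.concatenate([rho_to_real_vector(rho0.matrix), np.zeros(8)])
    sol = solve_ivp(rhs, (grid[0], grid[-1]), y0, method="LSODA",
                    t_eval=grid, rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise RuntimeError(f"OU integration failed: {sol.message}")
    states = np.array([real_vector_to_rho(y[:8]) for y in sol.y.T])
    meta = {"model": "classical_noise", "noise": "ou", "route": "auxiliary_operator",
            "alpha_prime": noise.alpha_prime, "tau_corr": noise.tau_corr,
            "solver": "LSODA", "rtol": RTOL, "atol": ATOL, "nfev": int(sol.nfev),
            "omega0": system.omega0, "delta0": system.delta0}
    return evolution_diagnostics(grid, states, meta)


def _evolve_ou_history(rho0: DensityMatrix, system, noise, grid) -> EvolutionResult:
    """Fixed-step Heun integration with trapezoid quadrature of the memory term.

    Second-order accurate; requires a uniform grid.  The memory state is the
    full rho history: K(t_k) is re-assembled at every step from the stored
    commutators, which keeps this route's discretization independent of the
    auxiliary-operator route (their mutual agreement is a test oracle).
    """
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt, rtol=1e-9, atol=0.0):
        raise ValueError("history route requires a uniform time grid")
    n = len(grid)
    c0 = noise.stationary_variance
    tau = noise.tau_corr
    h0 = 0.5 * system.omega0 * SIGMA_Z - 0.5 * system.delta0 * SIGMA_X

    u_dt = free_propagator(dt, system)
    u_dag = u_dt.conj().T
    decay = np.exp(-dt / tau)

    def comm_sz(m):
        return SIGMA_Z @ m - m @ SIGMA_Z

    def rotate(m):
        # one step of C-decay plus free rotation of a stored history term
        return decay * (u_dt @ m @ u_dag)

    states = np.empty((n, 2, 2), dtype=complex)
    states[0] = rho0.matrix
    rho = rho0.matrix.copy()
    # trapezoid over the stored history, evaluated incrementally in the
    # interaction picture: `full_sum` carries sum_{j<k} C(t_k-s_j) R(t_k-s_j) B_j
    # at unit weight, `first_node` the rotated B_0 whose weight must be halved
    full_sum = np.zeros((2, 2), dtype=complex)
    first_node = comm_sz(rho)  # B_0, rotated forward as time advances

    for k in range(n - 1):
        b_k = comm_sz(rho)
        kernel_now = c0 * dt * (full_sum - 0.5 * first_node + 0.5 * b_k)
        d1 = -1j * (h0 @ rho - rho @ h0) - comm_sz(kernel_now)
        rho_pred = rho + dt * d1

        full_next = rotate(full_sum + b_k)
        first_next = rotate(first_node)
        b_pred = comm_sz(rho_pred)
        kernel_next = c0 * dt * (full_next - 0.5 * first_next + 0.5 * b_pred)
        d2 = -1j * (h0 @ rho_pred - rho_pred @ h0) - comm_sz(kernel_next)

        rho = rho + 0.5 * dt * (d1 + d2)
        full_sum, first_node = full_next, first_next
        states[k + 1] = rho

    meta = {"model": "classical_noise", "noise": "ou", "route": "history_trapezoid",
            "alpha_prime": noise.alpha_prime, "tau_corr": noise.tau_corr,
            "solver": "heun_fixed_step", "dt": dt,
            "omega0": system.omega0, "delta0": system.delta0}
    return evolution_diagnostics(grid, states, meta)


def evolve_noise(
    rho0: DensityMatrix,
    system: SystemParams,
    noise: NoiseSpec,
    grid: np.ndarray,
    route: str = "auto",
) -> EvolutionResult:
    """Integrate the averaged classical-noise master equation over ``grid``.

    ``route`` selects the OU discretization: ``"auto"``/``"aux"`` for the
    adaptive auxiliary-operator ODE, ``"history"`` for the fixed-step
    history-quadrature scheme (uniform grids only).  White noise always uses
    the adaptive exact equation.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if noise.kind == "white":
        return _evolve_white(rho0, system, noise, grid)
    if route in ("auto", "aux"):
        return _evolve_ou_aux(rho0, system, noise, grid)
    if route == "history":
        return _evolve_ou_history(rho0, system, noise, grid)
    raise ValueError(f"unknown route {route!r}")
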