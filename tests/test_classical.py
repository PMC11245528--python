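import numpy as np
import pytest
from scipy.linalg import expm

from knockon.classical import (
    NoiseSpec,
    evolve_noise,
    free_propagator,
    ou_memory_rhs,
    white_rhs,
)
from knockon.core import (
    DensityMatrix,
    SystemParams,
    initial_superposition,
    system_hamiltonian,
)


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(kind="white")
    with pytest.raises(ValueError):
        NoiseSpec(kind="ou", alpha_prime=1e7)
    with pytest.raises(ValueError, match="kind"):
        NoiseSpec(kind="pink", alpha=1.0)
    assert NoiseSpec(kind="ou", alpha_prime=1e7,
                     tau_corr=5e-8).stationary_variance == pytest.approx(1e14)


@pytest.mark.parametrize("p, q", [(0.5, 0.5), (0.3, 0.2 - 0.1j), (1.0, 0.0)])
def test_white_generator_conserves_trace_exactly(p, q):
    rho = np.array([[p, q], [np.conj(q), 1 - p]], dtype=complex)
    d = white_rhs(0.0, rho, SystemParams(delta0=1e7, omega0=3e6),
                  NoiseSpec(kind="white", alpha=0.5e7))
    assert d[0, 0] + d[1, 1] == pytest.approx(0.0, abs=1e-12)
    # Hermiticity of the generator
    np.testing.assert_allclose(d, d.conj().T, atol=1e-9)


def test_white_population_transfer_bookkeeping(rho0):
    # d(rho00 - rho11)/dt = i delta0 (rho10 - rho01) under our sign convention
    rho = np.array([[0.6, 0.1 + 0.2j], [0.1 - 0.2j, 0.4]], dtype=complex)
    d0 = 1e7
    d = white_rhs(0.0, rho, SystemParams(delta0=d0, omega0=0.0),
                  NoiseSpec(kind="white", alpha=0.0))
    assert d[0, 0] - d[1, 1] == pytest.approx(1j * d0 * (rho[1, 0] - rho[0, 1]))


def test_white_alpha_zero_is_von_neumann(rho0):
    grid = np.linspace(0, 5e-7, 201)
    res = evolve_noise(rho0, SystemParams(delta0=1e7, omega0=3e6),
                       NoiseSpec(kind="white", alpha=0.0), grid)
    assert np.max(np.abs(res.purity - 1.0)) < 1e-9
    assert res.trace_drift < 1e-10


def test_white_closed_form_dephasing(rho0):
    w0, alpha = 1e7, 0.5e7
    grid = np.linspace(0, 10 / (2 * alpha), 801)
    res = evolve_noise(rho0, SystemParams(delta0=0.0, omega0=w0),
                       NoiseSpec(kind="white", alpha=alpha), grid)
    exact = 0.5 * np.exp(-(1j * w0 + 2 * alpha) * grid)
    assert np.max(np.abs(res.rho01 - exact)) < 1e-8
    # |rho01| reaches 1/(2e) at t = 1/(2 alpha) = 1e-7 s
    k = np.argmin(np.abs(grid - 1e-7))
    assert abs(res.rho01[k]) == pytest.approx(0.5 / np.e, rel=1e-6)


def test_free_propagator_identity_group_and_oracles():
    sys_ = SystemParams(delta0=1e7, omega0=3e6)
    np.testing.assert_allclose(free_propagator(0.0, sys_), np.eye(2))
    dt = 3e-8
    u = free_propagator(dt, sys_)
    np.testing.assert_allclose(u @ free_propagator(-dt, sys_), np.eye(2),
                               atol=1e-12)
    np.testing.assert_allclose(u @ u.conj().T, np.eye(2), atol=1e-12)
    h = system_hamiltonian(sys_)
    # two independent matrix-exponential routes
    np.testing.assert_allclose(u, expm(-1j * h * dt), atol=1e-12)
    vals, vecs = np.linalg.eigh(h)
    eig_route = vecs @ np.diag(np.exp(-1j * vals * dt)) @ vecs.conj().T
    np.testing.assert_allclose(u, eig_route, atol=1e-12)


def test_ou_strength_zero_is_von_neumann(rho0):
    grid = np.linspace(0, 5e-7, 201)
    res = evolve_noise(rho0, SystemParams(delta0=1e7, omega0=0.0),
                       NoiseSpec(kind="ou", alpha_prime=0.0, tau_corr=1e-8), grid)
    assert np.max(np.abs(res.purity - 1.0)) < 1e-9


def test_ou_routes_mutual_oracle(rho0):
    """History-quadrature and auxiliary-operator discretizations agree."""
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    ou = NoiseSpec(kind="ou", alpha_prime=0.5e7, tau_corr=5e-8)
    grid = np.linspace(0, 4e-7, 3201)
    aux = evolve_noise(rho0, sys_, ou, grid, route="aux")
    hist = evolve_noise(rho0, sys_, ou, grid, route="history")
    assert np.max(np.abs(aux.rho01 - hist.rho01)) < 1e-6
    assert hist.meta["route"] == "history_trapezoid"


def test_ou_memory_rhs_reduces_to_von_neumann_at_zero_kernel(rho0):
    sys_ = SystemParams(delta0=1e7, omega0=2e6)
    ou = NoiseSpec(kind="ou", alpha_prime=3e6, tau_corr=1e-8)
    drho, dk = ou_memory_rhs(0.0, rho0.matrix, np.zeros((2, 2)), sys_, ou)
    h = system_hamiltonian(sys_)
    np.testing.assert_allclose(drho, -1j * (h @ rho0.matrix - rho0.matrix @ h),
                               atol=1e-6)
    # kernel operator is sourced by C(0)[sz, rho]
    assert dk[0, 1] == pytest.approx(ou.stationary_variance * 2 * rho0.rho01)


def test_ou_white_limit_ladder(rho0):
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    alpha = 0.5e7
    grid = np.linspace(0, 1e-6, 801)
    white = evolve_noise(rho0, sys_, NoiseSpec(kind="white", alpha=alpha), grid)
    gaps = []
    for tau in (4e-8, 2e-8, 1e-8, 5e-9):
        ou = evolve_noise(rho0, sys_,
                          NoiseSpec(kind="ou", alpha_prime=alpha, tau_corr=tau),
                          grid)
        gaps.append(np.max(np.abs(ou.rho01 - white.rho01)))
    assert gaps[0] > gaps[1] > gaps[2] > gaps[3]


def test_ou_deviation_from_white_first_order_in_tau(rho0):
    """For small tau the OU-white gap scales linearly in tau."""
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    alpha = 0.5e7
    grid = np.linspace(0, 4e-7, 401)
    white = evolve_noise(rho0, sys_, NoiseSpec(kind="white", alpha=alpha), grid)

    def gap(tau):
        ou = evolve_noise(rho0, sys_,
                          NoiseSpec(kind="ou", alpha_prime=alpha, tau_corr=tau),
                          grid)
        return np.max(np.abs(ou.rho01 - white.rho01))

    ratio = gap(2e-9) / gap(1e-9)
    assert 1.7 < ratio < 2.3


def test_history_route_requires_uniform_grid(rho0):
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    ou = NoiseSpec(kind="ou", alpha_prime=1e6, tau_corr=1e-8)
    bad = np.concatenate([[0.0], np.geomspace(1e-9, 1e-7, 50)])
    with pytest.raises(ValueError, match="uniform"):
        evolve_noise(rho0, sys_, ou, bad, route="history")
    with pytest.raises(ValueError, match="route"):
        evolve_noise(rho0, sys_, ou, np.linspace(0, 1e-7, 11), route="magic")


def test_white_trace_conservation_at_printed_parameters(rho0):
    for d0 in (1e7, 1e8):
        grid = np.linspace(0, 1e-6, 501)
        res = evolve_noise(rho0, SystemParams(delta0=d0, omega0=0.0),
                           NoiseSpec(kind="white", alpha=0.5e7), grid)
        assert res.trace_drift < 1e-10
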