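import numpy as np
import pytest

from knockon.classical import NoiseSpec, evolve_noise, free_propagator
from knockon.core import SystemParams
from knockon.trajectories import (
    NoisePath,
    ensemble_average,
    run_trajectory,
    sample_ou_path,
    sample_white_increments,
)


def test_noise_path_validation():
    grid = np.linspace(0, 1e-7, 11)
    with pytest.raises(ValueError, match="kind"):
        NoisePath(times=grid, values=np.zeros(11), seed=0, kind="pink")
    with pytest.raises(ValueError, match="values"):
        NoisePath(times=grid, values=np.zeros(11), seed=0,
                  kind="white_increments")
    with pytest.raises(ValueError, match="uniform"):
        sample_ou_path(np.geomspace(1e-9, 1e-7, 20), 1e7, 1e-8, 0)


def test_ou_path_zero_strength_is_zero():
    grid = np.linspace(0, 1e-6, 64)
    path = sample_ou_path(grid, 0.0, 1e-8, 42)
    assert np.all(path.values == 0.0)


def test_ou_path_stationary_statistics():
    """Variance and lag autocovariance of a long stationary path match the
    stated kernel C(t) = (alpha'/2 tau) exp(-|t|/tau)."""
    ap, tau = 2e7, 1e-7
    dt = tau / 2
    n = 100_000
    grid = np.arange(n) * dt
    z = sample_ou_path(grid, ap, tau, seed=2024).values
    var_target = ap / (2 * tau)
    phi = np.exp(-dt / tau)
    # effective sample count for AR(1) second-moment estimates
    n_eff = n * (1 - phi**2) / (1 + phi**2)
    se_var = var_target * np.sqrt(2.0 / n_eff)
    assert abs(np.var(z) - var_target) < 3 * se_var
    assert abs(np.mean(z)) < 3 * np.sqrt(var_target / n_eff)
    for lag_steps in (1, 2, 4):  # lags tau/2, tau, 2*tau
        emp = np.mean(z[:-lag_steps] * z[lag_steps:])
        target = var_target * np.exp(-lag_steps * dt / tau)
        assert abs(emp - target) < 4 * se_var


def test_white_increment_law():
    grid = np.arange(100_001) * 1e-9
    dw = sample_white_increments(grid, alpha=1e7, seed=99).values
    n = len(dw)
    assert np.var(dw) / 1e-9 == pytest.approx(1.0, abs=3 * np.sqrt(2.0 / n))
    assert abs(np.mean(dw)) < 3 * np.sqrt(1e-9 / n)


def test_zero_path_trajectory_matches_free_propagation(rho0):
    grid = np.linspace(0, 5e-7, 51)
    sys_ = SystemParams(delta0=1e7, omega0=3e6)
    path = sample_ou_path(grid, 0.0, 1e-8, 0)
    res = run_trajectory(rho0, sys_, path)
    dt = grid[1] - grid[0]
    u = free_propagator(dt, sys_)
    rho = rho0.matrix
    for k in range(1, len(grid)):
        rho = u @ rho @ u.conj().T
        np.testing.assert_allclose(res.states[k], rho, atol=1e-12)


def test_each_trajectory_is_exactly_unitary(rho0):
    grid = np.linspace(0, 1e-6, 501)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    for path in (sample_white_increments(grid, 0.5e7, 1),
                 sample_ou_path(grid, 0.5e7, 1e-8, 1)):
        res = run_trajectory(rho0, sys_, path)
        assert np.max(np.abs(res.purity - 1.0)) < 1e-10
        assert res.trace_drift < 1e-12


def test_weak_ou_path_close_to_free_evolution(rho0):
    grid = np.linspace(0, 5e-7, 201)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    free = run_trajectory(rho0, sys_, sample_ou_path(grid, 0.0, 1e-8, 5))
    ap = 1e3  # very weak noise
    pert = run_trajectory(rho0, sys_, sample_ou_path(grid, ap, 1e-8, 5))
    # perturbative bound: phase deviation <= |z|_max * t
    zmax = np.max(np.abs(sample_ou_path(grid, ap, 1e-8, 5).values))
    assert np.max(np.abs(pert.rho01 - free.rho01)) <= 2 * zmax * grid[-1]


def test_ensemble_requires_two_members(rho0):
    grid = np.linspace(0, 1e-7, 11)
    with pytest.raises(ValueError, match="n >= 2"):
        ensemble_average(rho0, SystemParams(delta0=1e7),
                         NoiseSpec(kind="white", alpha=0.0), grid, n=1,
                         base_seed=0)


def test_ensemble_zero_noise_has_zero_standard_error(rho0):
    grid = np.linspace(0, 2e-7, 21)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    ens = ensemble_average(rho0, sys_, NoiseSpec(kind="white", alpha=0.0),
                           grid, n=2, base_seed=0)
    assert np.max(ens.se_re_rho01) == 0.0
    free = run_trajectory(rho0, sys_, sample_ou_path(grid, 0.0, 1e-8, 0))
    np.testing.assert_allclose(ens.mean_states, free.states, atol=1e-12)


def test_ensemble_deterministic_seeding(rho0):
    grid = np.linspace(0, 2e-7, 51)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    noise = NoiseSpec(kind="white", alpha=0.5e7)
    a = ensemble_average(rho0, sys_, noise, grid, n=64, base_seed=17)
    b = ensemble_average(rho0, sys_, noise, grid, n=64, base_seed=17)
    c = ensemble_average(rho0, sys_, noise, grid, n=64, base_seed=18)
    np.testing.assert_array_equal(a.mean_states, b.mean_states)
    assert np.max(np.abs(a.mean_states - c.mean_states)) > 0


def test_ensemble_block_path_equals_individual_trajectories(rho0):
    """The vectorized block propagation reproduces per-trajectory runs with
    the documented SeedSequence splitting rule."""
    grid = np.linspace(0, 3e-7, 61)
    sys_ = SystemParams(delta0=1e7, omega0=2e6)
    for noise in (NoiseSpec(kind="white", alpha=0.5e7),
                  NoiseSpec(kind="ou", alpha_prime=2e7, tau_corr=5e-8)):
        ens = ensemble_average(rho0, sys_, noise, grid, n=5, base_seed=23)
        children = np.random.SeedSequence(23).spawn(5)
        acc = np.zeros((len(grid), 2, 2), dtype=complex)
        for child in children:
            if noise.kind == "white":
                path = sample_white_increments(grid, noise.alpha, child)
            else:
                path = sample_ou_path(grid, noise.alpha_prime, noise.tau_corr,
                                      child)
            acc += run_trajectory(rho0, sys_, path).states
        np.testing.assert_allclose(ens.mean_states, acc / 5, atol=1e-13)


def test_standard_error_shrinks_as_root_n(rho0):
    grid = np.linspace(0, 5e-7, 101)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    noise = NoiseSpec(kind="white", alpha=0.5e7)
    se_small = ensemble_average(rho0, sys_, noise, grid, n=200,
                                base_seed=5).se_re_rho01[1:].mean()
    se_big = ensemble_average(rho0, sys_, noise, grid, n=800,
                              base_seed=5).se_re_rho01[1:].mean()
    assert se_small / se_big == pytest.approx(2.0, rel=0.2)


def test_dephasing_characteristic_function_oracle(rho0):
    """delta0 = 0: the ensemble coherence matches the Gaussian
    characteristic function E[exp(-2i sqrt(alpha) W_t)] = exp(-2 alpha t)."""
    alpha = 0.5e7
    grid = np.linspace(0, 2e-7, 201)
    sys_ = SystemParams(delta0=0.0, omega0=0.0)
    ens = ensemble_average(rho0, sys_, NoiseSpec(kind="white", alpha=alpha),
                           grid, n=5000, base_seed=31)
    exact = 0.5 * np.exp(-2 * alpha * grid)
    gap = np.abs(ens.rho01.real - exact)
    assert np.all(gap[1:] <= 3 * ens.se_re_rho01[1:] + 1e-4)


def test_coherence_loss_only_in_the_mean(rho0):
    """Per-trajectory |rho01| does not decay systematically; only the
    ensemble mean loses coherence."""
    grid = np.linspace(0, 1e-6, 501)
    sys_ = SystemParams(delta0=1e7, omega0=0.0)
    ens = ensemble_average(rho0, sys_, NoiseSpec(kind="white", alpha=0.5e7),
                           grid, n=400, base_seed=13)
    assert ens.mean_abs_rho01[-1] > 0.3      # individual coherences survive
    assert abs(ens.rho01[-1]) < 0.05         # the mean has dephased
    assert ens.meta["max_purity_defect"] < 1e-10


def test_ensemble_result_view_in_common_schema(rho0):
    grid = np.linspace(0, 2e-7, 21)
    ens = ensemble_average(rho0, SystemParams(delta0=1e7, omega0=0.0),
                           NoiseSpec(kind="white", alpha=0.5e7), grid, n=8,
                           base_seed=2)
    view = ens.to_evolution_result()
    assert view.meta["model"] == "trajectory_ensemble"
    assert view.meta["n_realizations"] == 8
    frame = view.to_frame()
    assert list(frame.columns)[0] == "t" and len(frame) == len(grid)
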