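"""Ohmic–Drude bath: spectral density, kernels, and Born–Markov coefficients.

The environment is an Ohmic bath of harmonic oscillators with a Lorentz–Drude
cutoff,

    J(omega) = (2 M gamma0 / pi) * omega * omega_c**2 / (omega_c**2 + omega**2),

extended to negative frequencies as an odd function.  The microscopic
oscillator parameters never appear individually: only the lumped prefactor
``M * gamma0`` matters downstream, and in practice the coupling is calibrated
so that the closed-form decay coefficient gamma = (pi/2) J(delta0) hits a
requested value (the comparison presets are specified by gamma directly).

Two routes to the Born–Markov coefficients (D, f, gamma) are provided:

* ``closed_form`` — the odd-J / high-temperature expressions
  gamma = (pi/2) J(delta0), D = gamma * coth(delta0 / 2 k_B T),
  f = 2 M gamma0 k_B T omega_c delta0 / (delta0**2 + omega_c**2);
  valid for beta * omega_c << 1 and refused when beta * omega_c >= 1.
* ``numeric`` — brute-force quadrature of the tau-integrals of the noise and
  dissipation kernels, used as the independent cross-check.

Quadrature conventions (documented so runs reproduce bit-for-bit): the
frequency integrals run over [0, 50 * max(omega_c, k_B T)] with scipy's
oscillatory QAWO rule plus an analytic Si/Ci tail for the truncated remainder;
the tau-integrals run over [0, 50 / omega_c] (the Drude kernels decay on
1/omega_c) on a composite Gauss–Legendre panel whose subdivision tracks the
fastest oscillation, max(delta0, omega_c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.special import sici

from .core import kelvin_to_rate

__all__ = [
    "BathSpec",
    "BornMarkovCoefficients",
    "spectral_density",
    "calibrate_coupling",
    "noise_kernel",
    "dissipation_kernel",
    "dissipation_kernel_closed_form",
    "born_markov_coefficients",
    "default_bath",
    "comparison_bath",
]

OMEGA_MAX_FACTOR = 50.0
TAU_MAX_FACTOR = 50.0
_GL_NODES = 160


class KernelQuadratureError(RuntimeError):
    """Raised when a kernel quadrature fails to converge."""


@dataclass(frozen=True)
class BathSpec:
    """Ohmic–Drude environment specification.

    Exactly one of ``coupling_prefactor`` (the lumped M*gamma0, dimensionless
    under the hbar=1 rate convention) or ``gamma_target`` (a decay rate in 1/s
    the coupling is calibrated to at a given delta0) must be supplied.

    ``temperature`` is the thermal rate k_B T / hbar in 1/s (use
    :func:`knockon.core.kelvin_to_rate` for Kelvin input).
    """

    omega_c: float
    temperature: float
    coupling_prefactor: float | None = None
    gamma_target: float | None = None

    def __post_init__(self) -> None:
        if self.omega_c <= 0:
            raise ValueError("omega_c must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if (self.coupling_prefactor is None) == (self.gamma_target is None):
            raise ValueError(
                "exactly one of coupling_prefactor / gamma_target must be supplied"
            )
        if self.coupling_prefactor is not None and self.coupling_prefactor <= 0:
            raise ValueError("coupling_prefactor must be positive")
        if self.gamma_target is not None and self.gamma_target <= 0:
            raise ValueError("gamma_target must be positive")

    @property
    def beta_omega_c(self) -> float:
        """The high-temperature control parameter beta * omega_c."""
        return self.omega_c / self.temperature

    def resolved(self, delta0: float) -> "BathSpec":
        """Return a spec with the coupling prefactor fixed.

        A calibrated bath needs the system's tunneling element to pin
        M*gamma0; a bath already carrying a prefactor is returned unchanged.
        """
        if self.coupling_prefactor is not None:
            return self
        prefactor = calibrate_coupling(self.gamma_target, delta0, self.omega_c)
        return BathSpec(
            omega_c=self.omega_c, temperature=self.temperature,
            coupling_prefactor=prefactor,
        )


@dataclass(frozen=True)
class BornMarkovCoefficients:
    """The coefficients of the Born–Markov master equation, all rates in 1/s.

    ``D`` multiplies the double-commutator decoherence term, ``f`` and
    ``gamma`` enter through zeta = f - i*gamma (decay and Lamb-shift terms).
    """

    D: float
    f: float
    gamma: float

    @property
    def zeta(self) -> complex:
        return self.f - 1j * self.gamma

    @classmethod
    def zero(cls) -> "BornMarkovCoefficients":
        return cls(D=0.0, f=0.0, gamma=0.0)


def spectral_density(omega: float, bath: BathSpec) -> float:
    """Ohmic–Drude spectral density J(omega), odd in omega, in 1/s."""
    if bath.coupling_prefactor is None:
        raise ValueError(
            "bath is calibrated by gamma_target; call bath.resolved(delta0) first"
        )
    w = np.asarray(omega, dtype=float)
    wc2 = bath.omega_c**2
    out = (2.0 * bath.coupling_prefactor / np.pi) * w * wc2 / (wc2 + w**2)
    return out if out.ndim else float(out)


def calibrate_coupling(gamma_target: float, delta0: float, omega_c: float) -> float:
    """Prefactor M*gamma0 such that (pi/2) J(delta0) equals gamma_target."""
    if gamma_target <= 0 or delta0 <= 0 or omega_c <= 0:
        raise ValueError("gamma_target, delta0 and omega_c must all be positive")
    return gamma_target * (delta0**2 + omega_c**2) / (delta0 * omega_c**2)


def _coth_over(omega: float, temperature: float) -> float:
    # coth(omega / 2T) with the integrable omega->0 limit handled via series
    x = omega / (2.0 * temperature)
    if x < 1e-8:
        return 1.0 / x if x > 0 else np.inf
    return 1.0 / np.tanh(x)


def _omega_max(bath: BathSpec) -> float:
    return OMEGA_MAX_FACTOR * max(bath.omega_c, bath.temperature)


def noise_kernel(tau: float, bath: BathSpec) -> float:
    """Noise kernel nu(tau) = int_0^inf J(w) coth(w/2k_BT) cos(w tau) dw.

    The combined integrand J*coth is smooth at the origin (J ~ w cancels the
    coth ~ 1/w divergence); the zero-point tail makes nu(0) log-divergent in
    the cutoff, which is why the truncation at 50*max(omega_c, k_BT) is part
    of the kernel's definition here.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    prefactor = bath.coupling_prefactor
    if prefactor is None:
        raise ValueError("resolve the bath coupling first (bath.resolved)")
    T = bath.temperature
    wc2 = bath.omega_c**2

    def smooth(w: float) -> float:
        if w == 0.0:
            return (2.0 * prefactor / np.pi) * wc2 / wc2 * 2.0 * T
        return (2.0 * prefactor / np.pi) * w * wc2 / (wc2 + w * w) * _coth_over(w, T)

    upper = _omega_max(bath)
    # natural magnitude of nu: the high-T kernel value 2*Mgamma0*k_BT*omega_c
    scale = 2.0 * prefactor * T * bath.omega_c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if tau == 0.0:
            val, err = quad(smooth, 0.0, upper, points=[bath.omega_c, T],
                            limit=400, epsabs=1e-10 * scale, epsrel=1e-10)
        else:
            val, err = quad(smooth, 0.0, upper, weight="cos", wvar=tau,
                            limit=400, maxp1=100,
                            epsabs=1e-10 * scale, epsrel=1e-10)
    if err > 1e-6 * max(scale, abs(val)):
        raise KernelQuadratureError(
            f"noise kernel quadrature failed at tau={tau!r}: "
            f"error estimate {err:g} vs scale {scale:g}"
        )
    if tau > 0.0:
        # analytic tail: beyond omega_max, J*coth ~ (2Mgamma0/pi) wc^2 / w,
        # so the remainder is -(2Mgamma0/pi) wc^2 * Ci(omega_max * tau)
        _, ci = sici(upper * tau)
        val -= (2.0 * prefactor / np.pi) * wc2 * ci
    return val


def dissipation_kernel(tau: float, bath: BathSpec) -> float:
    """Dissipation kernel eta(tau) = int_0^inf J(w) sin(w tau) dw."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0.0:
        return 0.0
    if bath.coupling_prefactor is None:
        raise ValueError("resolve the bath coupling first (bath.resolved)")
    upper = _omega_max(bath)
    scale = bath.coupling_prefactor * bath.omega_c**2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val, err = quad(lambda w: spectral_density(w, bath), 0.0, upper,
                        weight="sin", wvar=tau, limit=400, maxp1=100,
                        epsabs=1e-10 * scale, epsrel=1e-10)
    if err > 1e-6 * max(scale, abs(val)):
        raise KernelQuadratureError(
            f"dissipation kernel quadrature failed at tau={tau!r}: "
            f"error estimate {err:g} vs scale {scale:g}"
        )
    # analytic tail: J ~ (2Mgamma0/pi) wc^2 / w beyond the truncation, giving
    # (2Mgamma0/pi) wc^2 * (pi/2 - Si(omega_max * tau))
    si, _ = sici(upper * tau)
    val += (2.0 * bath.coupling_prefactor / np.pi) * bath.omega_c**2 * (0.5 * np.pi - si)
    return val


def dissipation_kernel_closed_form(tau: float, bath: BathSpec) -> float:
    """Contour-integral closed form eta(tau) = M*gamma0 * omega_c**2 * exp(-omega_c*tau).

    Valid for tau > 0; the numeric kernel is checked against this in tests.
    """
    if bath.coupling_prefactor is None:
        raise ValueError("resolve the bath coupling first (bath.resolved)")
    return bath.coupling_prefactor * bath.omega_c**2 * np.exp(-bath.omega_c * tau)


def _tau_panel(bath: BathSpec, delta0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    # composite Gauss-Legendre over [0, 50/omega_c]; the subdivision tracks the
    # fastest oscillation (delta0 can exceed omega_c for a slow Drude bath)
    tau_max = TAU_MAX_FACTOR / bath.omega_c
    n_osc = tau_max * (delta0 + bath.omega_c) / (2.0 * np.pi)
    m = int(max(20, np.ceil(4.0 * n_osc)))
    x, w = leggauss(8)
    edges = np.linspace(0.0, tau_max, m + 1)
    half = 0.5 * np.diff(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    taus = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    wts = (half[:, None] * w[None, :]).ravel()
    return taus, wts


def born_markov_coefficients(
    delta0: float, bath: BathSpec, mode: str = "closed_form"
) -> BornMarkovCoefficients:
    """Born–Markov coefficients (D, f, gamma) for tunneling element delta0.

    ``closed_form`` uses the odd-J delta-function collapse of the
    tau-integrals plus the high-temperature f; it warns for
    beta*omega_c > 0.1 and refuses beta*omega_c >= 1.  ``numeric``
    integrates the kernels over tau on the documented Gauss–Legendre panel.
    A calibrated bath is resolved against ``delta0`` internally.
    """
    if delta0 < 0:
        raise ValueError("delta0 must be non-negative")
    if mode not in ("closed_form", "numeric"):
        raise ValueError(f"unknown mode {mode!r}")
    if delta0 == 0.0:
        # sin(0) integrands vanish; only the dephasing coefficient survives
        rbath = bath if bath.coupling_prefactor is not None else None
        if rbath is None:
            raise ValueError("delta0=0 cannot be used with a gamma-calibrated bath")
        if mode == "closed_form":
            # lim_{w->0} J(w) coth(w/2T) * pi/2 = 2 M gamma0 T... the D integral
            # collapses onto the zero-frequency limit of J*coth/2 * pi
            D = rbath.coupling_prefactor * 2.0 * rbath.temperature
        else:
            taus, wts = _tau_panel(rbath, 0.0)
            D = float(np.sum(wts * np.array([noise_kernel(t, rbath) for t in taus])))
        return BornMarkovCoefficients(D=D, f=0.0, gamma=0.0)

    rbath = bath.resolved(delta0)
    beta_wc = rbath.beta_omega_c
    if mode == "closed_form":
        if beta_wc >= 1.0:
            raise ValueError(
                f"high-temperature closed forms invalid: beta*omega_c={beta_wc:.3g} >= 1"
            )
        if beta_wc > 0.1:
            warnings.warn(
                f"beta*omega_c={beta_wc:.3g} > 0.1: high-temperature closed forms "
                "are marginal", stacklevel=2,
            )
        gamma = 0.5 * np.pi * spectral_density(delta0, rbath)
        D = gamma * _coth_over(delta0, rbath.temperature)
        f = (
            2.0 * rbath.coupling_prefactor * rbath.temperature
            * rbath.omega_c * delta0 / (delta0**2 + rbath.omega_c**2)
        )
        return BornMarkovCoefficients(D=D, f=f, gamma=gamma)

    taus, wts = _tau_panel(rbath, delta0)
    nu = np.array([noise_kernel(t, rbath) for t in taus])
    eta = np.array([dissipation_kernel(t, rbath) for t in taus])
    D = float(np.sum(wts * nu * np.cos(delta0 * taus)))
    f = float(np.sum(wts * nu * np.sin(delta0 * taus)))
    gamma = float(np.sum(wts * eta * np.sin(delta0 * taus)))
    return BornMarkovCoefficients(D=D, f=f, gamma=gamma)


def default_bath() -> BathSpec:
    """Physiological default: T = 310 K, omega_c = 1e12 1/s, gamma-calibrated.

    beta*omega_c ~ 0.025, so the high-temperature closed forms apply.  In this
    regime D/gamma = coth(delta0/2k_BT) ~ 1e6–1e7 for hopping rates in the
    physiological window: the Born–Markov coherence decay is many orders of
    magnitude faster than the classical-noise rate (see docs/methods.md).
    """
    return BathSpec(omega_c=1e12, temperature=kelvin_to_rate(310.0),
                    gamma_target=0.5e7)


def comparison_bath() -> BathSpec:
    """Bath used by the figure presets for model comparison.

    The thermal rate is set to 1e8 1/s, the upper end of the ion-conduction
    window, so that the quantum-to-classical crossover of
    D/gamma = coth(delta0/2k_BT) spans the hopping sweep (coth ~ 20 at
    delta0 = 1e7 1/s down to ~2.2 at 1e8 1/s).  This is the regime in which
    the agreement between the Spin-Boson and white-noise pictures improves
    with hopping rate; at the physiological bath of :func:`default_bath`
    the comparison is degenerate (see docs/methods.md).  omega_c = 2e6 1/s
    keeps beta*omega_c = 0.02, so the closed forms remain valid.
    """
    return BathSpec(omega_c=2e6, temperature=1e8, gamma_target=0.5e7)
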