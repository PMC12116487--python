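"""Coupled Hopf oscillators in polar form, with pluggable coupling schemes.

The elementary unit is the supercritical Hopf oscillator

    dz/dt = (mu + i*omega + beta*|z|^2) z,      z = r e^{i theta},

whose stable limit cycle has amplitude sqrt(-mu/beta).  A bank of N such
oscillators interacts through complex lateral weights ``A_ij e^{i phi_ij}``
under one of four schemes:

``power``
    Oscillator j enters the equation of oscillator i raised to the frequency
    ratio ``omega_i/omega_j`` ("power coupling").  In polar form,

        dr_i/dt    += A_ij r_j^(w_i/w_j) cos[w_i (th_j/w_j - th_i/w_i
                                                  + phi_ij/(w_i w_j))]
        dth_i/dt   += (A_ij r_j^(w_i/w_j) / r_i) sin[ ... same argument ... ]

    which admits a fixed normalized phase difference ``theta_i/omega_i -
    theta_j/omega_j`` between oscillators of arbitrary frequencies.
``complex``
    Plain complex coupling ``A_ij e^{i phi_ij} z_j`` with no exponent scaling.
``linear_all`` / ``linear_nn``
    Real diffusive coupling ``k (x_j - x_i)`` on the real parts, all-to-all or
    restricted to the (index- or geometry-) adjacent pairs in the mask.

A scalar error drive ``epsilon * e(t)`` can force the real axis of every
oscillator, which is how the network is trained on a teaching signal.

Phases are stored *unwrapped*: the power-coupling argument depends on the
ratios ``theta/omega``, whose continuity in time would break under mod-2*pi
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError, InputError

__all__ = [
    "OMEGA_MIN",
    "R_FLOOR",
    "OscillatorBank",
    "LateralCoupling",
    "limit_cycle_amplitude",
    "coupling_drive",
    "step",
    "simulate",
    "normalized_phase_differences",
    "random_bank",
    "all_to_all_coupling",
]

#: Floor on intrinsic angular frequency (rad/s); adaptation and initialization
#: never go below 2*pi*0.05 (0.05 Hz).
OMEGA_MIN = 2.0 * np.pi * 0.05

#: Amplitude floor used to clamp the 1/r factor in the phase equation so that
#: transiently tiny amplitudes do not abort integration.
R_FLOOR = 1e-6

COUPLING_SCHEMES = ("power", "complex", "linear_all", "linear_nn")


@dataclass
class OscillatorBank:
    """State of N Hopf oscillators in polar coordinates.

    ``omega`` are intrinsic angular frequencies (rad/s, >= OMEGA_MIN),
    ``r`` amplitudes (>= 0) and ``theta`` unwrapped phases (rad).  ``mu`` and
    ``beta`` are the bifurcation and cubic coefficients shared by the bank;
    with ``mu > 0`` and ``beta < 0`` the uncoupled attractor amplitude is
    ``sqrt(-mu/beta)``.
    """

    omega: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    mu: float = 1.0
    beta: float = -20.0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float).ravel()
        self.r = np.asarray(self.r, dtype=float).ravel()
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        n = self.omega.size
        if self.r.size != n or self.theta.size != n:
            raise InputError("omega, r, theta must have equal length")
        if np.any(self.r < 0):
            raise InputError("amplitudes r must be nonnegative")
        if np.any(self.omega < OMEGA_MIN - 1e-12):
            raise InputError(
                f"intrinsic frequencies must be >= {OMEGA_MIN:.4g} rad/s"
            )

    @property
    def n(self) -> int:
        return self.omega.size

    @property
    def z(self) -> np.ndarray:
        """Complex state r*exp(i*theta)."""
        return self.r * np.exp(1j * self.theta)

    def copy(self) -> "OscillatorBank":
        return OscillatorBank(
            self.omega.copy(), self.r.copy(), self.theta.copy(), self.mu, self.beta
        )


@dataclass
class LateralCoupling:
    """Complex oscillator-to-oscillator weights plus a connectivity mask.

    The effective coupling gain between i and j is ``xi_w * A[i, j]`` with
    phase offset ``phi[i, j]``; ``mask`` marks which directed pairs exist (the
    diagonal is always off: sums run over j != i).  ``tau_w`` is the time
    constant of the Hebbian relaxation used during stage-1 training.
    """

    A: np.ndarray
    phi: np.ndarray
    mask: np.ndarray
    scheme: str = "power"
    xi_w: float = 1.0
    tau_w: float = 1.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scheme not in COUPLING_SCHEMES:
            raise InputError(f"unknown coupling scheme {self.scheme!r}")
        if self.A.shape != self.phi.shape or self.A.shape != self.mask.shape:
            raise InputError("A, phi, mask must share an (n, n) shape")
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise InputError("coupling matrices must be square")
        np.fill_diagonal(self.mask, False)
        if np.any(self.A[~self.mask] != 0):
            self.A = np.where(self.mask, self.A, 0.0)
        if np.any(self.A < 0):
            raise InputError("coupling magnitudes A must be nonnegative")
        if self.tau_w <= 0:
            raise InputError("tau_w must be positive")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def wprime(self) -> np.ndarray:
        """Complex lateral weight matrix ``A * exp(i*phi)`` (masked).

        The dynamics scale this by the coupling coefficient ``xi_w``.
        """
        return np.where(self.mask, self.A * np.exp(1j * self.phi), 0.0)

    def copy(self) -> "LateralCoupling":
        return LateralCoupling(
            self.A.copy(), self.phi.copy(), self.mask.copy(),
            self.scheme, self.xi_w, self.tau_w,
        )


def limit_cycle_amplitude(mu: float, beta: float) -> float:
    """Amplitude of the stable limit cycle of ``dr/dt = (mu + beta r^2) r``.

    Requires the supercritical regime ``mu > 0, beta < 0``; the nonzero fixed
    point is ``sqrt(-mu/beta)``.
    """
    if mu <= 0 or beta >= 0:
        raise InputError(
            f"no stable nonzero limit cycle for mu={mu}, beta={beta}; "
            "need mu > 0 and beta < 0"
        )
    return float(np.sqrt(-mu / beta))


def _power_drive(omega, r, theta, gain, phi):
    """Power-coupling contributions (dr_i, r_i*dtheta_i) as n-vectors."""
    w_i = omega[:, None]
    w_j = omega[None, :]
    rho = w_i / w_j
    # r_j ** (w_i/w_j), guarded for r_j == 0
    r_j = np.maximum(r[None, :], 0.0)
    with np.errstate(divide="ignore"):
        logr = np.log(np.where(r_j > 0, r_j, 1.0))
    pw = np.where(r_j > 0, np.exp(rho * logr), 0.0)
    arg = w_i * (
        theta[None, :] / w_j - theta[:, None] / w_i + phi / (w_i * w_j)
    )
    dr = np.sum(gain * pw * np.cos(arg), axis=1)
    dth_r = np.sum(gain * pw * np.sin(arg), axis=1)
    return dr, dth_r


def coupling_drive(
    bank: OscillatorBank, coupling: LateralCoupling | None
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling contributions to (dr/dt, dtheta/dt) for every oscillator.

    Returns a pair of length-n vectors; zeros when ``coupling`` is ``None`` or
    its mask is all-false.  The ``1/r_i`` factor in the phase equation is
    clamped at :data:`R_FLOOR`.
    """
    n = bank.n
    if coupling is None or not coupling.mask.any():
        z = np.zeros(n)
        return z, z.copy()
    if coupling.n != n:
        raise InputError(f"coupling is {coupling.n}x{coupling.n} for a bank of {n}")
    gain = np.where(coupling.mask, coupling.xi_w * coupling.A, 0.0)
    r_safe = np.maximum(bank.r, R_FLOOR)
    if coupling.scheme == "power":
        dr, dth_r = _power_drive(bank.omega, bank.r, bank.theta, gain, coupling.phi)
        return dr, dth_r / r_safe
    if coupling.scheme == "complex":
        arg = bank.theta[None, :] + coupling.phi - bank.theta[:, None]
        dr = np.sum(gain * bank.r[None, :] * np.cos(arg), axis=1)
        dth = np.sum(gain * bank.r[None, :] * np.sin(arg), axis=1) / r_safe
        return dr, dth
    # linear (diffusive) coupling on the real parts, forcing the real axis
    x = bank.r * np.cos(bank.theta)
    c = np.sum(gain * (x[None, :] - x[:, None]), axis=1)
    return c * np.cos(bank.theta), -c * np.sin(bank.theta) / r_safe


def _derivs(bank, coupling, error_drive, epsilon):
    """Right-hand side (dr/dt, dtheta/dt) of the full forced system."""
    cr, cth = coupling_drive(bank, coupling)
    r_safe = np.maximum(bank.r, R_FLOOR)
    dr = (bank.mu + bank.beta * bank.r**2) * bank.r + cr
    dth = bank.omega + cth
    if epsilon != 0.0 and error_drive != 0.0:
        f = epsilon * error_drive
        dr = dr + f * np.cos(bank.theta)
        dth = dth - f * np.sin(bank.theta) / r_safe
    return dr, dth


def step(
    bank: OscillatorBank,
    coupling: LateralCoupling | None = None,
    error_drive: float = 0.0,
    epsilon: float = 1.0,
    dt: float = 0.002,
    integrator: str = "rk4",
) -> OscillatorBank:
    """Advance the bank one time step and return the new state.

    ``error_drive`` is the scalar e(t), broadcast to every oscillator as a
    real-axis forcing ``epsilon * e(t)`` held constant over the step.  With
    ``error_drive=0`` this is the autonomous coupled system.  ``integrator``
    is ``'rk4'`` (fixed-step 4th-order Runge-Kutta) or ``'euler'``.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    if epsilon < 0:
        raise InputError("epsilon must be nonnegative")
    if integrator == "euler":
        dr, dth = _derivs(bank, coupling, error_drive, epsilon)
        r = bank.r + dt * dr
        theta = bank.theta + dt * dth
    elif integrator == "rk4":
        def f(r, theta):
            trial = replace(bank, omega=bank.omega, r=np.maximum(r, 0.0), theta=theta)
            return _derivs(trial, coupling, error_drive, epsilon)

        k1r, k1t = f(bank.r, bank.theta)
        k2r, k2t = f(bank.r + 0.5 * dt * k1r, bank.theta + 0.5 * dt * k1t)
        k3r, k3t = f(bank.r + 0.5 * dt * k2r, bank.theta + 0.5 * dt * k2t)
        k4r, k4t = f(bank.r + dt * k3r, bank.theta + dt * k3t)
        r = bank.r + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        theta = bank.theta + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
    else:
        raise InputError(f"unknown integrator {integrator!r}")
    r = np.maximum(r, 0.0)
    bad = ~(np.isfinite(r) & np.isfinite(theta))
    if bad.any():
        raise DivergenceError(
            f"non-finite state after step for oscillator(s) {np.flatnonzero(bad)}"
        )
    return OscillatorBank(bank.omega.copy(), r, theta, bank.mu, bank.beta)


def simulate(
    bank: OscillatorBank,
    coupling: LateralCoupling | None,
    duration: float,
    dt: float = 0.002,
    integrator: str = "rk4",
    record: bool = False,
):
    """Integrate the autonomous system for ``duration`` seconds.

    Returns the final bank, or ``(final_bank, r_history, theta_history)``
    arrays of shape ``(n_steps, n)`` when ``record`` is true.
    """
    n_steps = int(round(duration / dt))
    hist_r = np.empty((n_steps, bank.n)) if record else None
    hist_t = np.empty((n_steps, bank.n)) if record else None
    cur = bank
    for k in range(n_steps):
        cur = step(cur, coupling, 0.0, 0.0, dt, integrator)
        if record:
            hist_r[k] = cur.r
            hist_t[k] = cur.theta
    if record:
        return cur, hist_r, hist_t
    return cur


def normalized_phase_differences(bank: OscillatorBank) -> np.ndarray:
    """Pairwise normalized phase differences, in seconds.

    Entry (i, j) is ``theta_i/omega_i - theta_j/omega_j``; the matrix is
    antisymmetric with zero diagonal.  Under power coupling this quantity
    settles to a constant for every connected pair.
    """
    norm = bank.theta / bank.omega
    return norm[:, None] - norm[None, :]


def random_bank(
    n: int,
    seed: int,
    omega_range_hz: tuple[float, float] = (0.0, 10.0),
    mu: float = 1.0,
    beta: float = -20.0,
) -> OscillatorBank:
    """Seeded random initialization: r ~ U[0.1, 1], theta ~ U[0, 2*pi),
    omega uniform over ``omega_range_hz`` (floored at OMEGA_MIN)."""
    rng = np.random.default_rng(seed)
    lo, hi = omega_range_hz
    omega = np.maximum(2 * np.pi * rng.uniform(lo, hi, n), OMEGA_MIN)
    r = rng.uniform(0.1, 1.0, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return OscillatorBank(omega, r, theta, mu, beta)


def all_to_all_coupling(
    n: int,
    A0: float = 0.001,
    scheme: str = "power",
    xi_w: float = 1.0,
    tau_w: float = 1.0,
    seed: int | None = None,
) -> LateralCoupling:
    """All-to-all (off-diagonal) coupling with uniform initial magnitude.

    Angles are zero, or uniform in [0, 2*pi) when ``seed`` is given.  For
    ``scheme='linear_nn'`` the mask connects index-adjacent pairs only.
    """
    if scheme == "linear_nn":
        idx = np.arange(n)
        mask = np.abs(idx[:, None] - idx[None, :]) == 1
    else:
        mask = ~np.eye(n, dtype=bool)
    A = np.where(mask, A0, 0.0)
    if seed is None:
        phi = np.zeros((n, n))
    else:
        phi = np.random.default_rng(seed).uniform(0.0, 2 * np.pi, (n, n))
    return LateralCoupling(A, phi, mask, scheme, xi_w, tau_w)
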