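"""Stage-1 online training: adaptive frequencies, real readout, Hebbian coupling.

The oscillator bank is driven by the reconstruction error of a teaching
signal D(t).  At every sample the network output is the real linear readout

    s(t) = sum_i alpha_i cos(theta_i),        e(t) = D(t) - s(t),

and e(t) forces the real axis of every oscillator (gain ``epsilon``).  Three
quantities adapt online, all with the same error signal:

    intrinsic frequency   d(omega_j)/dt = -eta_omega * e(t) * sin(theta_j)
    real readout weight   d(alpha_j)/dt =  eta_alpha * e(t) * cos(theta_j)
    lateral weight        tau_w dW'_ij/dt = -W'_ij + z_i (z_j*)^(w_i/w_j)

The frequency rule is the classic adaptive-frequency-oscillator mechanism:
each oscillator is captured by, and then tracks, the spectral component of
the teacher nearest its own frequency, so the trained bank performs a
Fourier-like decomposition of the signal.

Updates are applied per sample (forward Euler locked to the sampling grid;
the teacher only exists at sample instants).  The order within a sample is:
compute s and e from the pre-step state, advance (r, theta) one Euler step,
then update omega, alpha and W' with that same e(t) and the post-step phases.
Learning rates are the per-sample rates at the reference 500 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import SCHEME_CODES, stage1_epoch
from .dynamics import (
    OMEGA_MIN,
    R_FLOOR,
    LateralCoupling,
    OscillatorBank,
    all_to_all_coupling,
    coupling_drive,
    random_bank,
)
from .errors import DivergenceError, InputError
from .signal import MultichannelSignal

__all__ = [
    "Stage1Config",
    "TrainingTrace",
    "Stage1Result",
    "stage1_output",
    "hebbian_update",
    "train_stage1",
    "collect_phases",
]


@dataclass
class Stage1Config:
    """Hyper-parameters of stage-1 training.

    Defaults are the reference settings: learning rates
    ``eta_omega = eta_alpha = 1e-4``, coupling coefficient ``xi_w = 1e-3``,
    initial real readout weight ``alpha0 = 0.2``, frequencies initialized
    uniformly over 0-10 Hz, 30 passes over the teaching signal.  ``epsilon``
    is the error-drive gain (the printed equations leave it free; 1.0 here).
    """

    seed: int
    eta_omega: float = 1e-4
    eta_alpha: float = 1e-4
    epsilon: float = 1.0
    epochs: int = 30
    alpha0: float = 0.2
    omega_range_hz: tuple[float, float] = (0.0, 10.0)
    f_max_hz: float = 20.0
    xi_w: float = 1e-3
    tau_w: float = 1.0
    mu: float = 1.0
    beta: float = -20.0
    hebbian: bool = True

    def __post_init__(self) -> None:
        if self.eta_omega <= 0 or self.eta_alpha <= 0:
            raise InputError("learning rates must be positive")
        if self.epochs < 1:
            raise InputError("epochs must be >= 1")
        if self.epsilon < 0:
            raise InputError("epsilon must be nonnegative")


@dataclass
class TrainingTrace:
    """Per-epoch RMSE of e(t) plus the final epoch's s(t) and e(t)."""

    epoch_rmse: np.ndarray
    reconstruction: np.ndarray
    error: np.ndarray


@dataclass
class Stage1Result:
    bank: OscillatorBank
    coupling: LateralCoupling
    alpha: np.ndarray
    trace: TrainingTrace
    config: Stage1Config | None = field(default=None, repr=False)


def stage1_output(bank: OscillatorBank, alpha: np.ndarray) -> float:
    """Real linear readout ``s = sum_i alpha_i cos(theta_i)``."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != bank.n:
        raise InputError(f"{alpha.size} weights for {bank.n} oscillators")
    return float(np.sum(alpha * np.cos(bank.theta)))


def _hebbian_target(omega: np.ndarray, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """``z_i (z_j*)^(w_i/w_j)`` in polar form, for unwrapped theta.

    The complex power is taken as ``r_j^(w_i/w_j) exp(-i theta_j w_i/w_j)``,
    i.e. magnitude and phase scaled separately, which is single-valued for
    unwrapped phases.
    """
    rho = omega[:, None] / omega[None, :]
    r_j = np.maximum(r[None, :], 0.0)
    with np.errstate(divide="ignore"):
        logr = np.log(np.where(r_j > 0, r_j, 1.0))
    mag = r[:, None] * np.where(r_j > 0, np.exp(rho * logr), 0.0)
    ang = theta[:, None] - rho * theta[None, :]
    return mag * np.exp(1j * ang)


def hebbian_update(
    coupling: LateralCoupling, bank: OscillatorBank, dt: float
) -> LateralCoupling:
    """One Euler step of the complex Hebbian relaxation of lateral weights.

    ``tau_w dW'/dt = -W' + z_i (z_j*)^(w_i/w_j)`` applied where the mask is
    true; magnitudes and angles are re-extracted from the updated W'.
    """
    if not coupling.mask.any():
        return coupling.copy()
    w = coupling.A * np.exp(1j * coupling.phi)
    target = _hebbian_target(bank.omega, bank.r, bank.theta)
    w = w + (dt / coupling.tau_w) * (-w + target)
    if not np.all(np.isfinite(w[coupling.mask])):
        raise DivergenceError("non-finite lateral weight after Hebbian update")
    A = np.where(coupling.mask, np.abs(w), 0.0)
    phi = np.where(coupling.mask, np.angle(w), 0.0)
    return LateralCoupling(
        A, phi, coupling.mask.copy(), coupling.scheme, coupling.xi_w, coupling.tau_w
    )


def _teacher_matrix(teacher: MultichannelSignal | np.ndarray, fs: float | None):
    if isinstance(teacher, MultichannelSignal):
        return teacher.data, teacher.fs
    arr = np.atleast_2d(np.asarray(teacher, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    if fs is None:
        raise InputError("fs must be given when the teacher is a bare array")
    return arr, fs


def train_stage1(
    teacher: MultichannelSignal | np.ndarray,
    n_osc: int,
    cfg: Stage1Config,
    coupling_scheme: str = "power",
    coupling: LateralCoupling | None = None,
    bank: OscillatorBank | None = None,
    fs: float | None = None,
) -> Stage1Result:
    """Run stage-1 online training and return the trained network.

    ``teacher`` is a single- or multi-channel signal; with several channels
    the mean error across channels drives the shared oscillator layer.  A
    ``coupling`` built elsewhere (e.g. from a spatial geometry) can be passed
    in; otherwise an all-to-all lateral matrix with initial magnitude 0.001 is
    used.  Only magnitudes/angles change during training, never the mask.
    """
    D, fs = _teacher_matrix(teacher, fs)
    n_t = D.shape[0]
    if n_t == 0:
        raise InputError("teacher signal is empty")
    if n_osc < 1:
        raise InputError("need at least one oscillator")
    dt = 1.0 / fs

    if bank is None:
        bank = random_bank(n_osc, cfg.seed, cfg.omega_range_hz, cfg.mu, cfg.beta)
    else:
        bank = bank.copy()
    if coupling is None:
        coupling = all_to_all_coupling(
            n_osc, A0=0.001, scheme=coupling_scheme,
            xi_w=cfg.xi_w, tau_w=cfg.tau_w, seed=cfg.seed + 1,
        )
    else:
        coupling = coupling.copy()
    if coupling.n != bank.n:
        raise InputError("coupling size does not match oscillator count")

    omega = bank.omega.copy()
    r = bank.r.copy()
    theta = bank.theta.copy()
    alpha = np.full(bank.n, cfg.alpha0, dtype=float)
    wre = np.where(coupling.mask, coupling.A * np.cos(coupling.phi), 0.0)
    wim = np.where(coupling.mask, coupling.A * np.sin(coupling.phi), 0.0)
    mask = coupling.mask
    use_hebb = cfg.hebbian and bool(mask.any())

    omega_hi = 2 * np.pi * (cfg.f_max_hz + 5.0)
    rmse = np.empty(cfg.epochs)
    s_trace = np.empty(n_t)
    e_trace = np.empty(n_t)
    D_mean = D.mean(axis=1)
    scheme_code = SCHEME_CODES[coupling.scheme]

    for epoch in range(cfg.epochs):
        last = epoch == cfg.epochs - 1
        sq = stage1_epoch(
            D_mean, dt, cfg.mu, cfg.beta, cfg.epsilon,
            cfg.eta_omega, cfg.eta_alpha, omega, r, theta, alpha,
            wre, wim, mask, coupling.xi_w, coupling.tau_w,
            scheme_code, use_hebb, OMEGA_MIN, omega_hi,
            s_trace, e_trace, last,
        )
        if not (np.isfinite(sq) and np.all(np.isfinite(omega))
                and np.all(np.isfinite(alpha)) and np.all(np.isfinite(r))
                and np.all(np.isfinite(theta))):
            raise DivergenceError(f"training diverged in epoch {epoch}")
        rmse[epoch] = np.sqrt(sq / n_t)

    trained_bank = OscillatorBank(omega, r, theta, cfg.mu, cfg.beta)
    w = wre + 1j * wim
    trained_coupling = LateralCoupling(
        np.where(mask, np.abs(w), 0.0), np.where(mask, np.angle(w), 0.0),
        mask.copy(), coupling.scheme, coupling.xi_w, coupling.tau_w,
    )
    trace = TrainingTrace(rmse, s_trace, e_trace)
    return Stage1Result(trained_bank, trained_coupling, alpha, trace, cfg)


def collect_phases(
    result: Stage1Result,
    teacher: MultichannelSignal | np.ndarray,
    fs: float | None = None,
    epsilon: float | None = None,
) -> tuple[np.ndarray, np.ndarray, OscillatorBank]:
    """Record the driven phase trajectory over the training window.

    All learned parameters are frozen; the network runs one more pass over
    the teacher, still driven by the stage-1 error signal, and the phases
    (and amplitudes) at every sample are recorded.  These entrained
    trajectories are the regressors for stage-2 readout training, and the
    returned final state is the seamless starting point for free-running
    generation.
    """
    D, fs = _teacher_matrix(teacher, fs)
    n_t = D.shape[0]
    cfg = result.config
    eps = (cfg.epsilon if cfg is not None else 1.0) if epsilon is None else epsilon
    dt = 1.0 / fs
    bank = result.bank.copy()
    coupling = result.coupling
    alpha = result.alpha
    theta_hist = np.empty((n_t, bank.n))
    r_hist = np.empty((n_t, bank.n))
    omega = bank.omega
    r = bank.r.copy()
    theta = bank.theta.copy()
    for k in range(n_t):
        theta_hist[k] = theta
        r_hist[k] = r
        cos_th = np.cos(theta)
        s = float(alpha @ cos_th)
        e = float(np.mean(D[k]) - s)
        trial = OscillatorBank(omega, r, theta, bank.mu, bank.beta)
        cdr, cdth = coupling_drive(trial, coupling)
        r_safe = np.maximum(r, R_FLOOR)
        f = eps * e
        dr = (bank.mu + bank.beta * r * r) * r + cdr + f * cos_th
        dth = omega + cdth - f * np.sin(theta) / r_safe
        r = np.maximum(r + dt * dr, 0.0)
        theta = theta + dt * dth
    final = OscillatorBank(omega.copy(), r, theta, bank.mu, bank.beta)
    return theta_hist, r_hist, final
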