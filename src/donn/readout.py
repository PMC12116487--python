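"""Stage-2 feed-forward readouts: complex linear weights and a hidden layer.

Both readouts map oscillator phases (not amplitudes: on the attractor the
amplitude is constant and absorbed into the weight magnitudes) to output
channels.

Complex linear readout
    ``Yp_i(t) = Re( sum_j K_ij e^{i xi_ij} e^{i theta_j(t)} )
              = sum_j K_ij cos(theta_j(t) + xi_ij)``
    trained by full-batch gradient descent on summed squared error with
    separate rates for magnitudes (eta_K) and angles (eta_xi).

Hidden-layer readout
    A complex first layer acts on the unit-modulus oscillator outputs
    ``e^{i theta}``; its real part passes through a layer of tanh neurons and
    a real second layer:

        h  = tanh( Re(W_in e^{i theta}) + b_h )
        Yp = act( W_out h + b_o ) * output_scale

    with ``act`` either tanh (targets are pre-scaled to max-abs 0.9 so they
    stay inside the tanh range) or identity.  Trained by full-batch gradient
    descent on mean squared error, optionally with classical momentum.
    Passing a mixture of sinusoids through the tanh nonlinearity generates
    inter-modulation harmonics (sums and differences of the oscillator
    frequencies), which is why this readout can reconstruct spectral content
    absent from the oscillator set itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, InputError

__all__ = [
    "ComplexLinearReadout",
    "HiddenReadout",
    "init_linear_readout",
    "init_hidden_readout",
    "linear_forward",
    "linear_loss_grads",
    "train_linear",
    "hidden_forward",
    "hidden_loss_grads",
    "train_hidden",
    "harmonic_enrichment_demo",
]


@dataclass
class ComplexLinearReadout:
    """Magnitudes K (>= 0) and angles xi of complex feed-forward weights,
    both of shape ``(n_channels, n_osc)``."""

    K: np.ndarray
    xi: np.ndarray
    eta_K: float = 3e-5
    eta_xi: float = 1e-6
    epochs: int = 5000

    def __post_init__(self) -> None:
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        if self.K.shape != self.xi.shape:
            raise InputError("K and xi must have the same shape")
        if not np.all(np.isfinite(self.K)):
            raise InputError("K must be finite")
        # fold negative magnitudes into the angle
        neg = self.K < 0
        if neg.any():
            self.K = np.abs(self.K)
            self.xi = np.where(neg, self.xi + np.pi, self.xi)

    @property
    def n_channels(self) -> int:
        return self.K.shape[0]

    @property
    def n_osc(self) -> int:
        return self.K.shape[1]

    def copy(self) -> "ComplexLinearReadout":
        return ComplexLinearReadout(
            self.K.copy(), self.xi.copy(), self.eta_K, self.eta_xi, self.epochs
        )


def init_linear_readout(
    n_channels: int, n_osc: int, seed: int, **kw
) -> ComplexLinearReadout:
    """Seeded initialization: K ~ U[0, 0.1], xi ~ U[0, 2*pi)."""
    rng = np.random.default_rng(seed)
    return ComplexLinearReadout(
        rng.uniform(0.0, 0.1, (n_channels, n_osc)),
        rng.uniform(0.0, 2 * np.pi, (n_channels, n_osc)),
        **kw,
    )


def linear_forward(readout: ComplexLinearReadout, theta: np.ndarray) -> np.ndarray:
    """Per-channel output for phases ``theta`` of shape (n_osc,) or (n_t, n_osc)."""
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    if th.shape[-1] != readout.n_osc:
        raise InputError(
            f"phases for {th.shape[-1]} oscillators, readout has {readout.n_osc}"
        )
    # (n_t, n_ch): sum_j K_ij cos(theta_tj + xi_ij)
    out = np.stack(
        [np.cos(th + readout.xi[i]) @ readout.K[i] for i in range(readout.n_channels)],
        axis=1,
    )
    return out if np.asarray(theta).ndim == 2 else out[0]


def linear_loss_grads(
    readout: ComplexLinearReadout, theta: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Summed-squared-error loss ``0.5 sum_t,i (Yd - Yp)^2`` and its gradients
    with respect to K and xi."""
    th = np.atleast_2d(theta)
    yd = np.atleast_2d(np.asarray(target, dtype=float))
    if yd.ndim == 2 and yd.shape[0] == 1 and th.shape[0] > 1:
        yd = yd.T
    yp = linear_forward(readout, th)
    err = yd - yp
    loss = 0.5 * float(np.sum(err**2))
    dK = np.empty_like(readout.K)
    dxi = np.empty_like(readout.xi)
    for i in range(readout.n_channels):
        c = np.cos(th + readout.xi[i])
        s = np.sin(th + readout.xi[i])
        dK[i] = -(c.T @ err[:, i])
        dxi[i] = readout.K[i] * (s.T @ err[:, i])
    return loss, dK, dxi


def train_linear(
    readout: ComplexLinearReadout,
    theta_timeseries: np.ndarray,
    target: np.ndarray,
    epochs: int | None = None,
) -> ComplexLinearReadout:
    """Batch gradient descent on the complex linear readout.

    Per epoch:  ``K += eta_K * sum_t (Yd-Yp) cos(theta+xi)`` and
    ``xi -= eta_xi * K * sum_t (Yd-Yp) sin(theta+xi)``.  Raises
    :class:`DivergenceError` when the loss increases for 10 consecutive
    epochs.  Negative magnitudes are folded into the angles on return.
    """
    th = np.atleast_2d(np.asarray(theta_timeseries, dtype=float))
    yd = np.atleast_2d(np.asarray(target, dtype=float))
    if yd.shape[0] == 1 and th.shape[0] > 1:
        yd = yd.T
    if yd.shape[0] != th.shape[0]:
        raise InputError("phase trajectory and target lengths differ")
    K = readout.K.copy()
    xi = readout.xi.copy()
    n_epochs = readout.epochs if epochs is None else epochs
    best = np.inf
    rising = 0
    for epoch in range(n_epochs):
        loss = 0.0
        for i in range(K.shape[0]):
            c = np.cos(th + xi[i])
            err = yd[:, i] - c @ K[i]
            loss += float(err @ err)
            gK = c.T @ err
            gxi = K[i] * (np.sin(th + xi[i]).T @ err)
            K[i] = K[i] + readout.eta_K * gK
            xi[i] = xi[i] - readout.eta_xi * gxi
        best = min(best, loss)
        # two-orders-of-magnitude sustained growth = genuine divergence;
        # transient momentum/oscillation humps stay well below this
        rising = rising + 1 if loss > 100.0 * best + 1e-300 else 0
        if rising >= 10:
            raise DivergenceError(
                f"linear readout training diverging at epoch {epoch}; "
                "reduce eta_K/eta_xi"
            )
    return ComplexLinearReadout(K, xi, readout.eta_K, readout.eta_xi, n_epochs)


@dataclass
class HiddenReadout:
    """Two-layer readout: complex first layer, tanh hidden units, real output.

    ``W_in`` is complex of shape ``(n_hidden, n_osc)``; ``W_out`` real of
    shape ``(n_channels, n_hidden)``.  ``output_scale`` is the per-channel
    factor that maps the network's (tanh-bounded) output back to signal
    units.  ``complex_input=False`` selects the pure-real variant whose first
    layer sees ``cos(theta)`` only.
    """

    W_in: np.ndarray
    b_h: np.ndarray
    W_out: np.ndarray
    b_o: np.ndarray
    output_activation: str = "tanh"
    eta_h: float = 1e-3
    eta_o: float = 1e-3
    epochs: int = 2000
    momentum: float = 0.9
    output_scale: np.ndarray = field(default=None)
    complex_input: bool = True
    optimizer: str = "sgd"

    def __post_init__(self) -> None:
        self.W_in = np.atleast_2d(np.asarray(self.W_in, dtype=complex))
        self.b_h = np.asarray(self.b_h, dtype=float).ravel()
        self.W_out = np.atleast_2d(np.asarray(self.W_out, dtype=float))
        self.b_o = np.asarray(self.b_o, dtype=float).ravel()
        if self.output_activation not in ("tanh", "identity"):
            raise InputError(f"unknown output activation {self.output_activation!r}")
        n_h = self.W_in.shape[0]
        if self.b_h.size != n_h or self.W_out.shape[1] != n_h:
            raise InputError("hidden-layer shapes are inconsistent")
        if self.W_out.shape[0] != self.b_o.size:
            raise InputError("output-layer shapes are inconsistent")
        if self.output_scale is None:
            self.output_scale = np.ones(self.W_out.shape[0])
        self.output_scale = np.asarray(self.output_scale, dtype=float).ravel()
        if np.any(self.output_scale <= 0):
            raise InputError("output_scale must be positive per channel")
        if self.optimizer not in ("sgd", "adam"):
            raise InputError(f"unknown optimizer {self.optimizer!r}")

    @property
    def n_osc(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W_out.shape[0]

    def copy(self) -> "HiddenReadout":
        return HiddenReadout(
            self.W_in.copy(), self.b_h.copy(), self.W_out.copy(), self.b_o.copy(),
            self.output_activation, self.eta_h, self.eta_o, self.epochs,
            self.momentum, self.output_scale.copy(), self.complex_input,
            self.optimizer,
        )


def init_hidden_readout(
    n_channels: int, n_osc: int, n_hidden: int, seed: int, **kw
) -> HiddenReadout:
    """Seeded initialization: real/imag first-layer parts and output weights
    uniform in [-0.1, 0.1], zero biases."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-0.1, 0.1, (n_hidden, n_osc))
    b = rng.uniform(-0.1, 0.1, (n_hidden, n_osc))
    W_out = rng.uniform(-0.1, 0.1, (n_channels, n_hidden))
    return HiddenReadout(
        a + 1j * b, np.zeros(n_hidden), W_out, np.zeros(n_channels), **kw
    )


def _hidden_pre(readout: HiddenReadout, th: np.ndarray) -> np.ndarray:
    a = readout.W_in.real
    b = readout.W_in.imag
    pre = np.cos(th) @ a.T + readout.b_h
    if readout.complex_input:
        pre = pre - np.sin(th) @ b.T
    return pre


def hidden_forward(readout: HiddenReadout, theta: np.ndarray) -> np.ndarray:
    """Forward pass; phases of shape (n_osc,) or (n_t, n_osc)."""
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    if th.shape[-1] != readout.n_osc:
        raise InputError(
            f"phases for {th.shape[-1]} oscillators, readout has {readout.n_osc}"
        )
    h = np.tanh(_hidden_pre(readout, th))
    pre_o = h @ readout.W_out.T + readout.b_o
    y = np.tanh(pre_o) if readout.output_activation == "tanh" else pre_o
    out = y * readout.output_scale
    return out if np.asarray(theta).ndim == 2 else out[0]


def hidden_loss_grads(readout: HiddenReadout, theta: np.ndarray, target: np.ndarray):
    """Mean-squared-error loss in scaled output units and its gradients.

    Returns ``(loss, grads)`` where ``grads`` is a dict with keys
    ``a, b, b_h, W_out, b_o`` (``a``/``b`` are the real/imaginary parts of
    the first layer).  The target is compared in scaled space, i.e. against
    ``target / output_scale``.
    """
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    yd = np.atleast_2d(np.asarray(target, dtype=float))
    if yd.shape[0] == 1 and th.shape[0] > 1:
        yd = yd.T
    n_t = th.shape[0]
    cos_t = np.cos(th)
    sin_t = np.sin(th)
    pre_h = _hidden_pre(readout, th)
    h = np.tanh(pre_h)
    pre_o = h @ readout.W_out.T + readout.b_o
    if readout.output_activation == "tanh":
        y = np.tanh(pre_o)
        dact = 1.0 - y**2
    else:
        y = pre_o
        dact = np.ones_like(y)
    err = yd / readout.output_scale - y
    loss = float(np.mean(err**2))
    gy = (-2.0 / err.size) * err * dact  # dL/d pre_o
    gW_out = gy.T @ h
    gb_o = gy.sum(axis=0)
    gh = (gy @ readout.W_out) * (1.0 - h**2)  # dL/d pre_h
    ga = gh.T @ cos_t
    gb = -(gh.T @ sin_t) if readout.complex_input else np.zeros_like(ga)
    gb_h = gh.sum(axis=0)
    return loss, {"a": ga, "b": gb, "b_h": gb_h, "W_out": gW_out, "b_o": gb_o}


def train_hidden(
    readout: HiddenReadout,
    theta_timeseries: np.ndarray,
    target: np.ndarray,
    epochs: int | None = None,
    set_scale: bool = True,
) -> HiddenReadout:
    """Full-batch gradient descent (with momentum) through both layers.

    When ``set_scale`` is true the per-channel ``output_scale`` is set to
    ``max|target| / 0.9`` so the scaled target stays inside the tanh range.
    Raises :class:`DivergenceError` when the loss rises for 10 consecutive
    epochs.
    """
    out = readout.copy()
    th = np.atleast_2d(np.asarray(theta_timeseries, dtype=float))
    yd = np.atleast_2d(np.asarray(target, dtype=float))
    if yd.shape[0] == 1 and th.shape[0] > 1:
        yd = yd.T
    if yd.shape[0] != th.shape[0]:
        raise InputError("phase trajectory and target lengths differ")
    if set_scale:
        scale = np.max(np.abs(yd), axis=0) / 0.9
        out.output_scale = np.where(scale > 0, scale, 1.0)
    n_epochs = out.epochs if epochs is None else epochs
    keys = ("a", "b", "b_h", "W_out", "b_o")
    rate = {"a": out.eta_h, "b": out.eta_h, "b_h": out.eta_h,
            "W_out": out.eta_o, "b_o": out.eta_o}
    vel = {k: 0.0 for k in keys}
    m1 = {k: 0.0 for k in keys}
    m2 = {k: 0.0 for k in keys}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    best = np.inf
    rising = 0
    for epoch in range(n_epochs):
        loss, g = hidden_loss_grads(out, th, yd)
        if not np.isfinite(loss):
            raise DivergenceError(f"hidden readout diverged at epoch {epoch}")
        best = min(best, loss)
        rising = rising + 1 if loss > 100.0 * best + 1e-300 else 0
        if rising >= 10:
            raise DivergenceError(
                f"hidden readout training diverging at epoch {epoch}; "
                "reduce eta_h/eta_o"
            )
        if out.optimizer == "adam":
            t_ad = epoch + 1
            for k in keys:
                m1[k] = beta1 * m1[k] + (1 - beta1) * g[k]
                m2[k] = beta2 * m2[k] + (1 - beta2) * g[k] ** 2
                mhat = m1[k] / (1 - beta1**t_ad)
                vhat = m2[k] / (1 - beta2**t_ad)
                vel[k] = -rate[k] * mhat / (np.sqrt(vhat) + adam_eps)
        else:
            mom = out.momentum
            for k in keys:
                vel[k] = mom * vel[k] - rate[k] * g[k]
        out.W_in = out.W_in + vel["a"] + 1j * vel["b"]
        out.b_h = out.b_h + vel["b_h"]
        out.W_out = out.W_out + vel["W_out"]
        out.b_o = out.b_o + vel["b_o"]
    return out


def harmonic_enrichment_demo(
    n_osc: int = 3,
    teacher: np.ndarray | None = None,
    fs: float = 500.0,
    seconds: float = 10.0,
    osc_freqs_hz: np.ndarray | None = None,
    n_hidden: int = 32,
    seed: int = 0,
    linear_epochs: int = 5000,
    hidden_epochs: int = 4000,
    eta_hidden: float = 1e-2,
) -> tuple[float, float]:
    """Reconstruction RMSE of linear vs hidden readout on a harmonic-rich
    teacher under identical (ideal) phase trajectories.

    By default the teacher is a square-like wave (odd harmonics 1-7 of 2 Hz,
    amplitudes 1/k) and the oscillator set carries only 2, 6 and 10 Hz, so
    the 14 Hz component is unreachable for the linear readout but reachable
    for the hidden one through tanh inter-modulation.
    """
    t = np.arange(int(round(seconds * fs))) / fs
    if osc_freqs_hz is None:
        osc_freqs_hz = np.array([2.0, 6.0, 10.0])[:n_osc]
    if teacher is None:
        teacher = sum((1.0 / k) * np.sin(2 * np.pi * 2.0 * k * t) for k in (1, 3, 5, 7))
    theta = 2 * np.pi * np.asarray(osc_freqs_hz)[None, :] * t[:, None]
    lin = init_linear_readout(1, len(osc_freqs_hz), seed)
    lin = train_linear(lin, theta, teacher[:, None], epochs=linear_epochs)
    rmse_lin = float(np.sqrt(np.mean((teacher - linear_forward(lin, theta)[:, 0]) ** 2)))
    hid = init_hidden_readout(
        1, len(osc_freqs_hz), n_hidden, seed,
        eta_h=eta_hidden, eta_o=eta_hidden, epochs=hidden_epochs,
        output_activation="tanh",
    )
    hid = train_hidden(hid, theta, teacher[:, None])
    rmse_hid = float(np.sqrt(np.mean((teacher - hidden_forward(hid, theta)[:, 0]) ** 2)))
    return rmse_lin, rmse_hid
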