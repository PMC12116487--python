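"""Free-running generation and the end-to-end fit/predict pipeline.

After the two training stages, the oscillator network runs autonomously
(no error drive) from the state it reached at the end of the training
window; the trained readout converts the unfolding phases into signal.
Because nothing is reset at the train/test boundary, the generated
continuation is seamless with the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import LateralCoupling, OscillatorBank, step
from .errors import InputError
from .metrics import MetricsReport, report
from .readout import (
    ComplexLinearReadout,
    HiddenReadout,
    hidden_forward,
    init_hidden_readout,
    init_linear_readout,
    linear_forward,
    train_hidden,
    train_linear,
)
from .signal import MultichannelSignal
from .stage1 import Stage1Config, Stage1Result, collect_phases, train_stage1

__all__ = ["run_free", "fit_predict", "PipelineConfig", "PredictionResult"]


def _readout_forward(readout, theta):
    if isinstance(readout, ComplexLinearReadout):
        return linear_forward(readout, theta)
    if isinstance(readout, HiddenReadout):
        return hidden_forward(readout, theta)
    return readout.forward(theta)  # duck-typed (multi-electrode model)


def run_free(
    bank: OscillatorBank,
    coupling: LateralCoupling | None,
    readout,
    duration: float,
    fs: float,
    integrator: str = "rk4",
    labels: list[str] | None = None,
) -> tuple[MultichannelSignal, OscillatorBank]:
    """Integrate the trained autonomous system and read out per sample.

    The first emitted sample is the readout of the *current* state (the
    train/test boundary); subsequent samples follow at 1/fs steps.  Returns
    the generated signal and the final oscillator state.  Deterministic:
    no randomness enters generation.
    """
    n = int(round(duration * fs))
    dt = 1.0 / fs
    cur = bank.copy()
    first = np.atleast_1d(_readout_forward(readout, cur.theta))
    out = np.empty((n, first.size))
    for k in range(n):
        out[k] = np.atleast_1d(_readout_forward(readout, cur.theta))
        cur = step(cur, coupling, 0.0, 0.0, dt, integrator)
    if labels is None:
        labels = [f"gen{i}" for i in range(first.size)]
    sig = MultichannelSignal(
        out if n else np.empty((0, first.size)), fs, labels,
        {"generator": "run_free", "integrator": integrator},
    )
    return sig, cur


@dataclass
class PipelineConfig:
    """End-to-end settings for :func:`fit_predict`.

    ``n_osc`` oscillators are trained on the input (stage 1), a readout of
    ``readout_kind`` ('linear' or 'hidden') is fitted on the driven phase
    trajectory (stage 2), and the continuation is generated autonomously.
    """

    stage1: Stage1Config
    n_osc: int = 20
    readout_kind: str = "linear"
    n_hidden: int = 100
    linear_epochs: int = 5000
    hidden_epochs: int = 2000
    eta_hidden: float = 1e-2
    integrator: str = "rk4"

    def __post_init__(self) -> None:
        if self.readout_kind not in ("linear", "hidden"):
            raise InputError(f"unknown readout kind {self.readout_kind!r}")


@dataclass
class PredictionResult:
    """Everything :func:`fit_predict` produces."""

    reconstruction: MultichannelSignal
    continuation: MultichannelSignal
    truth: MultichannelSignal
    report: MetricsReport
    stage1: Stage1Result = field(repr=False)
    readout: object = field(repr=False)
    boundary_bank: OscillatorBank = field(repr=False)


def fit_predict(
    signal: MultichannelSignal,
    cfg: PipelineConfig,
    train_seconds: float = 10.0,
    test_seconds: float = 5.0,
) -> PredictionResult:
    """Train on an initial window, then generate and score the continuation.

    The input must cover ``train_seconds + test_seconds``; both segments are
    assumed to come from the same dynamical regime.  Returns the training-
    window reconstruction, the free-running continuation, and a metrics
    report comparing the continuation against the held-out truth.
    """
    fs = signal.fs
    n_train = int(round(train_seconds * fs))
    n_test = int(round(test_seconds * fs))
    if signal.n_samples < n_train + n_test:
        raise InputError(
            f"signal has {signal.n_samples} samples; need at least "
            f"{n_train + n_test} for {train_seconds} s train + {test_seconds} s test"
        )
    train = MultichannelSignal(
        signal.data[:n_train], fs, list(signal.labels), dict(signal.meta)
    )
    truth = MultichannelSignal(
        signal.data[n_train : n_train + n_test], fs, list(signal.labels),
        dict(signal.meta),
    )

    s1 = train_stage1(train, cfg.n_osc, cfg.stage1)
    theta_hist, _, boundary = collect_phases(s1, train)

    target = train.data
    if cfg.readout_kind == "linear":
        ro = init_linear_readout(
            signal.n_channels, cfg.n_osc, cfg.stage1.seed + 2,
            epochs=cfg.linear_epochs,
        )
        ro = train_linear(ro, theta_hist, target)
    else:
        ro = init_hidden_readout(
            signal.n_channels, cfg.n_osc, cfg.n_hidden, cfg.stage1.seed + 2,
            eta_h=cfg.eta_hidden, eta_o=cfg.eta_hidden, epochs=cfg.hidden_epochs,
        )
        ro = train_hidden(ro, theta_hist, target)

    recon = MultichannelSignal(
        np.atleast_2d(_readout_forward(ro, theta_hist)), fs, list(signal.labels),
        {"role": "reconstruction"},
    )
    continuation, final = run_free(
        boundary, s1.coupling, ro, test_seconds, fs,
        integrator=cfg.integrator, labels=list(signal.labels),
    )
    rep = report(continuation, truth, fs) if n_test else None
    return PredictionResult(recon, continuation, truth, rep, s1, ro, boundary)
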