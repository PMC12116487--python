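"""Shared fixtures.

The expensive artefacts (a fully trained stage-1 network and a complete
fit/predict run at the reference settings) are session-scoped and reused by
the unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from donn import PipelineConfig, Stage1Config, fit_predict, preset


TONES3_FREQS = (2.0, 5.0, 8.0)


@pytest.fixture(scope="session")
def tones3_15s():
    """Unit-amplitude 2/5/8 Hz mixture: 10 s train + 5 s held-out test."""
    return preset("tones3", seconds=15.0, seed=0)


@pytest.fixture(scope="session")
def pipeline_result(tones3_15s):
    """Full reference pipeline on the 3-tone fixture.

    Stage 1 at the reference settings (20 oscillators, 30 epochs,
    eta = 1e-4, xi_w = 1e-3, alpha0 = 0.2), stage-2 complex linear readout
    (5000 epochs, eta_K = 3e-5, eta_xi = 1e-6), 5 s free-running generation.
    """
    cfg = PipelineConfig(stage1=Stage1Config(seed=1), n_osc=20,
                         readout_kind="linear")
    return fit_predict(tones3_15s, cfg, train_seconds=10.0, test_seconds=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
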