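"""Synthetic band-limited oscillatory signals for offline testing.

Generators for the kind of content the oscillator network assumes: mixtures
of sinusoids in the 0.1-20 Hz band, 1/f ("pink") background noise, and
spatially mixed multichannel combinations.  Every generator is a pure
function of its arguments including the seed, and stores its ground truth
(component frequencies/amplitudes/phases, mixing matrix) in the signal's
``meta`` so tests can score recovery without re-deriving anything.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .signal import MultichannelSignal

__all__ = [
    "sinusoid_mixture",
    "pink_noise_eeg",
    "multichannel_mixture",
    "preset",
    "PRESETS",
]


def sinusoid_mixture(
    freqs_hz,
    amps=None,
    phases=None,
    fs: float = 500.0,
    seconds: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synth",
) -> MultichannelSignal:
    """Single-channel sum of sinusoids plus optional white noise.

    ``x(t) = sum_k a_k sin(2 pi f_k t + p_k) + noise_sd * N(0, 1)``.
    Component lists must be equal length; an empty list yields silence.
    """
    freqs = np.asarray(freqs_hz, dtype=float).ravel()
    amps = np.ones_like(freqs) if amps is None else np.asarray(amps, dtype=float).ravel()
    phases = (
        np.zeros_like(freqs) if phases is None else np.asarray(phases, dtype=float).ravel()
    )
    if not (freqs.size == amps.size == phases.size):
        raise InputError("freqs, amps, phases must have equal length")
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise InputError(f"frequencies must lie in (0, fs/2) = (0, {fs / 2})")
    n = int(round(seconds * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a, p in zip(freqs, amps, phases):
        x += a * np.sin(2 * np.pi * f * t + p)
    if noise_sd > 0:
        x = x + noise_sd * np.random.default_rng(seed).standard_normal(n)
    meta = {
        "generator": "sinusoid_mixture",
        "freqs_hz": freqs.tolist(),
        "amps": amps.tolist(),
        "phases": phases.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return MultichannelSignal(x[:, None], fs, [label], meta)


def pink_noise_eeg(
    fs: float = 500.0,
    seconds: float = 10.0,
    band: tuple[float, float] = (0.1, 20.0),
    seed: int = 0,
) -> MultichannelSignal:
    """Band-limited 1/f Gaussian noise, zero mean and unit variance.

    White Gaussian noise is shaped in the frequency domain with amplitude
    ``f^(-1/2)`` inside ``band`` and zero outside, then renormalized.
    """
    if not (0 < band[0] < band[1] < fs / 2):
        raise InputError(f"band must lie inside (0, fs/2), got {band}")
    n = int(round(seconds * fs))
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    sel = (f >= band[0]) & (f <= band[1])
    shape[sel] = f[sel] ** -0.5
    x = np.fft.irfft(spec * shape, n)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    meta = {"generator": "pink_noise_eeg", "band": list(band), "seed": seed}
    return MultichannelSignal(x[:, None], fs, ["pink"], meta)


def multichannel_mixture(
    n_channels: int,
    sources: list[dict],
    mixing,
    fs: float = 500.0,
    seconds: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MultichannelSignal:
    """Spatially mixed multichannel signal: ``channels = mixing @ sources``.

    Each source is a component-set dict with keys ``freqs_hz`` and optional
    ``amps``/``phases`` (as accepted by :func:`sinusoid_mixture`).  Per-channel
    white noise of standard deviation ``noise_sd`` is added on top.  The
    mixing matrix and source definitions are stored in ``meta``.
    """
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if mixing.shape != (n_channels, len(sources)):
        raise InputError(
            f"mixing must be {n_channels}x{len(sources)}, got {mixing.shape}"
        )
    src = np.column_stack(
        [
            sinusoid_mixture(
                s["freqs_hz"], s.get("amps"), s.get("phases"), fs, seconds,
                noise_sd=0.0, seed=seed,
            ).data[:, 0]
            for s in sources
        ]
    ) if sources else np.zeros((int(round(seconds * fs)), 0))
    data = src @ mixing.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    meta = {
        "generator": "multichannel_mixture",
        "sources": sources,
        "mixing": mixing.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    labels = [f"ch{i}" for i in range(n_channels)]
    return MultichannelSignal(data, fs, labels, meta)


def _tones3(fs, seconds, seed):
    return sinusoid_mixture([2.0, 5.0, 8.0], fs=fs, seconds=seconds, seed=seed,
                            label="tones3")


def _tones5_noise(fs, seconds, seed):
    freqs = [0.5, 3.0, 7.5, 12.0, 18.0]
    amps = [1.0, 0.8, 0.6, 0.5, 0.4]
    sig = sinusoid_mixture(freqs, amps, fs=fs, seconds=seconds, seed=seed,
                           label="tones5")
    tone_power = 0.5 * float(np.sum(np.square(amps)))
    noise = pink_noise_eeg(fs, seconds, seed=seed + 1).data[:, 0]
    # 10 dB signal-to-noise ratio
    noise_sd = np.sqrt(tone_power / 10.0)
    data = sig.data[:, 0] + noise_sd * noise
    meta = dict(sig.meta)
    meta.update({"preset": "tones5_noise", "snr_db": 10.0, "noise_sd": noise_sd})
    return MultichannelSignal(data[:, None], fs, ["tones5"], meta)


def _harmonics(fs, seconds, seed):
    ks = [1, 3, 5, 7]
    return sinusoid_mixture(
        [2.0 * k for k in ks], [1.0 / k for k in ks],
        fs=fs, seconds=seconds, seed=seed, label="harmonics",
    )


def _spatial8(fs, seconds, seed):
    sources = [
        {"freqs_hz": [2.0], "amps": [1.0]},
        {"freqs_hz": [5.0], "amps": [1.0]},
        {"freqs_hz": [8.0], "amps": [1.0]},
    ]
    rng = np.random.default_rng(seed)
    mixing = rng.uniform(0.2, 1.0, (8, 3))
    return multichannel_mixture(8, sources, mixing, fs, seconds, noise_sd=0.0,
                                seed=seed)


PRESETS = {
    "tones3": _tones3,
    "tones5_noise": _tones5_noise,
    "harmonics": _harmonics,
    "spatial8": _spatial8,
}


def preset(
    name: str, fs: float = 500.0, seconds: float = 10.0, seed: int = 0
) -> MultichannelSignal:
    """Named fixture signals used throughout the test suite.

    ``tones3``: unit-amplitude 2/5/8 Hz mixture.  ``tones5_noise``: five
    tones over 0.5-18 Hz on pink background at 10 dB SNR.  ``harmonics``:
    square-like odd-harmonic wave (1/k amplitudes).  ``spatial8``:
    8 channels mixing three sinusoidal sources.
    """
    try:
        fn = PRESETS[name]
    except KeyError:
        raise InputError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return fn(fs, seconds, seed)
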