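"""Shared helpers: seeding and noise synthesis."""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a master seed and a stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def one_over_f_noise(n_samples: int, rng: np.random.Generator, exponent: float = 1.0,
                     size=()) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent amplitude spectrum, unit variance.

    `size` prepends leading axes (e.g. channels); time is always the last axis.
    """
    shape = tuple(size) + (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def ou_process(n_samples: int, fs: float, rng: np.random.Generator,
               tau_s: float = 0.3) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck process (correlation time tau_s)."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau_s * fs))
    b = np.sqrt(1.0 - a * a)
    innov = rng.standard_normal(n_samples)
    innov[0] /= b  # stationary start
    return lfilter([b], [1.0, -a], innov)
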