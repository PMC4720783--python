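"""Render oscillator phases as a multichannel recording with 1/f background."""

from __future__ import annotations

import numpy as np

from ..session.types import REGIONS, Recording
from .kuramoto import OscillatorNetwork


def default_montage(n_channels: int = 64) -> dict[str, str]:
    """Deterministic montage: E1..En split into six contiguous region blocks."""
    names = [f"E{i + 1}" for i in range(n_channels)]
    bounds = np.linspace(0, n_channels, len(REGIONS) + 1).astype(int)
    montage = {}
    for r_idx, region in enumerate(REGIONS):
        for i in range(bounds[r_idx], bounds[r_idx + 1]):
            montage[names[i]] = region
    return montage


def pink_noise(n_channels: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std


def render_recording(times: np.ndarray, phases: np.ndarray,
                     network: OscillatorNetwork, rate: float,
                     amplitudes: np.ndarray | float = 1.0,
                     noise_snr: float | None = 10.0,
                     seed: int = 0) -> Recording:
    """Map one oscillator per channel to A_i sin(theta_i) plus 1/f noise.

    ``noise_snr`` is the in-channel signal-to-noise ratio in dB; None renders
    noiselessly. Phases sampled on the integration grid are linearly
    interpolated onto the output rate.
    """
    n = phases.shape[0]
    if n != network.n:
        raise ValueError("one oscillator per channel required")
    max_f = np.max(np.abs(network.omega)) / (2 * np.pi)
    if rate < 4 * max_f:
        raise ValueError(f"rate {rate} below 4x max carrier {max_f:.3g} Hz")
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n,))

    dt_grid = np.diff(times)
    if dt_grid.size and np.allclose(dt_grid, 1.0 / rate, rtol=1e-6):
        theta = phases  # stored grid already matches the output rate
    else:
        t_out = np.arange(times[0], times[-1], 1.0 / rate)
        # interpolate unwrapped phases channel-wise (continuous in time)
        theta = np.stack([np.interp(t_out, times, phases[i]) for i in range(n)])
    samples = amplitudes[:, None] * np.sin(theta)

    if noise_snr is not None and np.any(amplitudes > 0):
        rng = np.random.default_rng(seed)
        noise = pink_noise(n, samples.shape[1], rng)
        sig_power = 0.5 * amplitudes ** 2
        noise_power = sig_power / (10.0 ** (noise_snr / 10.0))
        samples = samples + np.sqrt(noise_power)[:, None] * noise

    montage = default_montage(n)
    names = list(montage.keys())
    return Recording(samples, rate, names, montage)
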