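"""Additive BOLD noise: white, cardiac, respiratory and low-frequency drift.

White noise is zero-mean Gaussian with a single amplitude (its SD, in
percent-signal units). Each structured component is a sinusoid with a
nominal frequency and amplitude; per realization the frequency and
amplitude are jittered multiplicatively by uniform(-1, 1) times the jitter
fraction, and the phase is drawn uniformly — so every run of the noise
model is a fresh draw, as in repeated scans.

The low/mid/high presets are parameter bundles whose realized SNR against
the default noise-free bar-sweep signal spans the range observed in typical
visual-cortex measurements (roughly +5 dB down to -4 dB for a single
acquisition). SNR is reported as 20*log10(rms(signal)/rms(noise)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NoiseComponentSpec",
    "NoiseSpec",
    "generate_noise",
    "noise_preset",
    "measure_snr",
]


@dataclass(frozen=True)
class NoiseComponentSpec:
    kind: str  # "cardiac" | "respiratory" | "drift"
    frequency_hz: float
    amplitude: float  # percent-signal units (sinusoid amplitude)
    freq_jitter: float = 0.0
    amp_jitter: float = 0.0

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("component frequency must be positive")
        if self.amplitude < 0 or self.freq_jitter < 0 or self.amp_jitter < 0:
            raise ValueError("amplitude and jitters must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    white_amplitude: float = 0.0  # SD of the Gaussian term, percent-signal
    components: Sequence[NoiseComponentSpec] = field(default=())
    seed: int | None = None

    def __post_init__(self):
        if self.white_amplitude < 0:
            raise ValueError("white_amplitude must be non-negative")

    @property
    def is_silent(self) -> bool:
        return self.white_amplitude == 0 and all(
            c.amplitude == 0 for c in self.components
        )


def generate_noise(
    spec: NoiseSpec, n_frames: int, dt: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One noise realization of length ``n_frames`` sampled at ``dt`` seconds.

    A pure function of (spec, n_frames, dt, seed): passing no ``rng`` seeds
    a fresh generator from ``spec.seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(n_frames) * dt
    out = np.zeros(n_frames)
    if spec.white_amplitude > 0:
        out += rng.normal(0.0, spec.white_amplitude, size=n_frames)
    for comp in spec.components:
        f = comp.frequency_hz * (1.0 + rng.uniform(-1, 1) * comp.freq_jitter)
        a = comp.amplitude * (1.0 + rng.uniform(-1, 1) * comp.amp_jitter)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if a > 0:
            out += a * np.sin(2.0 * np.pi * f * t + phase)
    return out


# Preset amplitudes (percent-signal units) calibrated once against the rms of
# the default noise-free bar-sweep signal (10% peak modulation) so that the
# realized single-acquisition SNRs land near +5.3 / -0.5 / -4.3 dB for
# low / mid / high, matching the span seen in occipital on/off measurements.
_PRESET_AMPLITUDES = {
    # level: (white SD, cardiac A, respiratory A, drift A); variance split
    # white 50%, cardiac 15%, respiratory 15%, drift 20%
    "low": (1.656, 1.283, 1.283, 1.481),
    "mid": (3.230, 2.502, 2.502, 2.889),
    "high": (4.991, 3.866, 3.866, 4.464),
}

_COMPONENT_FREQS = {"cardiac": 1.2, "respiratory": 0.3, "drift": 0.01}


def noise_preset(level: str, seed: int | None = None) -> NoiseSpec:
    """Calibrated low / mid / high noise bundles (or 'none' for silence)."""
    if level == "none":
        return NoiseSpec(white_amplitude=0.0, components=(), seed=seed)
    if level not in _PRESET_AMPLITUDES:
        raise ValueError(f"unknown noise level: {level!r} (low|mid|high|none)")
    white, cardiac, resp, drift = _PRESET_AMPLITUDES[level]
    comps = (
        NoiseComponentSpec("cardiac", _COMPONENT_FREQS["cardiac"], cardiac, 0.1, 0.2),
        NoiseComponentSpec(
            "respiratory", _COMPONENT_FREQS["respiratory"], resp, 0.1, 0.2
        ),
        NoiseComponentSpec("drift", _COMPONENT_FREQS["drift"], drift, 0.3, 0.2),
    )
    return NoiseSpec(white_amplitude=white, components=comps, seed=seed)


def with_seed(spec: NoiseSpec, seed: int | None) -> NoiseSpec:
    return replace(spec, seed=seed)


def measure_snr(signal: np.ndarray, noise: np.ndarray) -> float:
    """SNR in dB: 20*log10(rms(signal) / rms(noise))."""
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if signal.shape != noise.shape:
        raise ValueError("signal and noise must have equal length")
    rms_noise = np.sqrt(np.mean(noise**2))
    if rms_noise == 0:
        raise ValueError("noise is all zero: SNR is infinite")
    rms_signal = np.sqrt(np.mean(signal**2))
    return float(20.0 * np.log10(rms_signal / rms_noise))
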