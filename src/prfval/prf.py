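"""Receptive-field models evaluated on the visual-field grid.

The population receptive field (pRF) is a 2-D sensitivity profile over the
stimulus field. Two families are provided: an (optionally elliptical)
Gaussian, and a difference-of-Gaussians (center minus scaled surround).
Fields are unnormalized — the peak equals the gain — because the linear
forward model absorbs overall scale into a fitted gain anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import VisualFieldGrid

__all__ = [
    "GaussianPRF",
    "DoGPRF",
    "evaluate_gaussian",
    "evaluate_dog",
    "cartesian_to_polar",
    "polar_to_cartesian",
]


@dataclass(frozen=True)
class GaussianPRF:
    """Gaussian receptive field: center (x0, y0) deg, axis SDs sigma_major >=
    sigma_minor (deg), major-axis angle theta (radians, CCW from +x), and a
    unitless gain. A circular pRF has sigma_major == sigma_minor; its theta
    is meaningless and normalized to 0."""

    x0: float
    y0: float
    sigma_major: float
    sigma_minor: float | None = None
    theta: float = 0.0
    gain: float = 1.0

    def __post_init__(self):
        if self.sigma_minor is None:
            object.__setattr__(self, "sigma_minor", self.sigma_major)
        if self.sigma_minor <= 0 or self.sigma_major <= 0:
            raise ValueError("pRF sigmas must be positive")
        if self.sigma_major < self.sigma_minor:
            raise ValueError("sigma_major must be >= sigma_minor")
        if self.is_circular and self.theta != 0.0:
            object.__setattr__(self, "theta", 0.0)

    @property
    def is_circular(self) -> bool:
        return self.sigma_major == self.sigma_minor

    @property
    def sigma(self) -> float:
        """1-SD radius of a circular pRF (the reported pRF size)."""
        return self.sigma_major


@dataclass(frozen=True)
class DoGPRF:
    """Difference of Gaussians: center Gaussian minus ``rel_amplitude`` times
    a surround Gaussian sharing the center location."""

    center: GaussianPRF
    surround_sigma_major: float
    surround_sigma_minor: float | None = None
    surround_theta: float = 0.0
    rel_amplitude: float = 0.5

    def __post_init__(self):
        if self.surround_sigma_minor is None:
            object.__setattr__(self, "surround_sigma_minor", self.surround_sigma_major)
        if self.surround_sigma_major <= 0 or self.surround_sigma_minor <= 0:
            raise ValueError("surround sigmas must be positive")
        if self.rel_amplitude < 0:
            raise ValueError("rel_amplitude must be >= 0")

    @property
    def gain(self) -> float:
        return self.center.gain


def _gauss_field(X, Y, x0, y0, s_major, s_minor, theta, gain):
    ct, st = np.cos(theta), np.sin(theta)
    dx, dy = X - x0, Y - y0
    u = dx * ct + dy * st      # along major axis
    v = -dx * st + dy * ct     # along minor axis
    return gain * np.exp(-0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2))


def evaluate_gaussian(prf: GaussianPRF, grid: VisualFieldGrid) -> np.ndarray:
    """Sample the Gaussian pRF on the grid; returns (n_rows, n_cols)."""
    X, Y = grid.mesh_deg()
    return _gauss_field(
        X, Y, prf.x0, prf.y0, prf.sigma_major, prf.sigma_minor, prf.theta, prf.gain
    )


def evaluate_dog(dog: DoGPRF, grid: VisualFieldGrid) -> np.ndarray:
    """Sample the DoG pRF: center field minus rel_amplitude * surround field."""
    X, Y = grid.mesh_deg()
    c = dog.center
    center = _gauss_field(
        X, Y, c.x0, c.y0, c.sigma_major, c.sigma_minor, c.theta, c.gain
    )
    surround = _gauss_field(
        X,
        Y,
        c.x0,
        c.y0,
        dog.surround_sigma_major,
        dog.surround_sigma_minor,
        dog.surround_theta,
        c.gain,
    )
    return center - dog.rel_amplitude * surround


def evaluate_field(prf, grid: VisualFieldGrid) -> np.ndarray:
    """Evaluate either pRF family on the grid."""
    if isinstance(prf, GaussianPRF):
        return evaluate_gaussian(prf, grid)
    if isinstance(prf, DoGPRF):
        return evaluate_dog(prf, grid)
    raise TypeError(f"unsupported pRF type: {type(prf).__name__}")


def cartesian_to_polar(x0, y0):
    """(x, y) deg -> (eccentricity deg, polar angle rad); origin -> (0, 0)."""
    x0, y0 = np.asarray(x0, dtype=float), np.asarray(y0, dtype=float)
    return np.hypot(x0, y0), np.arctan2(y0, x0)


def polar_to_cartesian(eccentricity, polar_angle):
    ecc = np.asarray(eccentricity, dtype=float)
    ang = np.asarray(polar_angle, dtype=float)
    return ecc * np.cos(ang), ecc * np.sin(ang)
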