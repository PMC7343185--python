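"""Hemodynamic response function (HRF) kernels.

Two parametric families are supported:

* ``two_gamma`` — the canonical difference of two Gamma densities,
  ``h(t) = gampdf(t; a1, b1) - c * gampdf(t; a2, b2)``, where the second
  Gamma models the post-stimulus undershoot (c = 0 gives a literal single
  Gamma).
* ``boynton`` — a delayed single Gamma with integer shape ``n``, time
  constant ``tau`` and onset ``delay``; all-positive (no undershoot).

Kernels are sampled at interval ``dt`` over ``duration_sec`` and normalized
to unit sum, so convolution preserves the signal mean and HRF mismatch
perturbs only the *shape* of the response, never its overall gain (gain is a
free parameter of the fit in any case). ``width_scale`` dilates the time
axis — h(t / w) — before renormalization, which scales both FWHM and
time-to-peak by w; it is the controlled mechanism used for HRF width
(mismatch) experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = ["HRFSpec", "sample_hrf", "scale_width", "default_hrf_set", "fwhm"]


@dataclass(frozen=True)
class HRFSpec:
    form: str = "two_gamma"  # "two_gamma" | "boynton"
    # two_gamma parameters (shape a, rate beta for each Gamma, relative scale c)
    a1: float = 6.0
    beta1: float = 1.0
    a2: float = 16.0
    beta2: float = 1.0
    c: float = 1.0 / 6.0
    # boynton parameters
    n: int = 3
    tau: float = 1.08
    delay: float = 2.05
    # sampling
    width_scale: float = 1.0
    dt: float = 1.0
    duration_sec: float = 40.0

    def __post_init__(self):
        if self.form not in ("two_gamma", "boynton"):
            raise ValueError(f"unknown HRF form: {self.form!r}")
        if min(self.a1, self.beta1, self.a2, self.beta2, self.tau) <= 0:
            raise ValueError("Gamma shape/rate/time constants must be positive")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _unnormalized(spec: HRFSpec, t: np.ndarray) -> np.ndarray:
    ts = t / spec.width_scale
    if spec.form == "two_gamma":
        peak = stats.gamma.pdf(ts, spec.a1, scale=1.0 / spec.beta1)
        undershoot = stats.gamma.pdf(ts, spec.a2, scale=1.0 / spec.beta2)
        return peak - spec.c * undershoot
    # boynton: delayed Gamma with integer shape, strictly non-negative
    shifted = ts - spec.delay
    h = np.zeros_like(ts)
    pos = shifted > 0
    x = shifted[pos] / spec.tau
    h[pos] = x ** (spec.n - 1) * np.exp(-x)
    return h


def sample_hrf(spec: HRFSpec) -> np.ndarray:
    """Sample the kernel at ``spec.dt`` over ``spec.duration_sec``, unit sum.

    Rejects degenerate parameterizations whose raw sum is not positive
    (e.g. an undershoot scaling that cancels the response).
    """
    if spec.duration_sec < 20:
        raise ValueError("kernel support must be >= 20 s to cover the response")
    n = int(round(spec.duration_sec / spec.dt))
    t = np.arange(n) * spec.dt
    h = _unnormalized(spec, t)
    total = h.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate HRF parameterization: kernel sum <= 0")
    return h / total


def scale_width(spec: HRFSpec, factor: float) -> HRFSpec:
    """Time-dilate the kernel by ``factor`` (FWHM and peak time scale by it)."""
    if factor <= 0:
        raise ValueError("width factor must be positive")
    return replace(spec, width_scale=spec.width_scale * factor)


def fwhm(spec: HRFSpec, dt: float = 0.01) -> float:
    """Full width at half maximum of the finely-sampled kernel, seconds."""
    fine = replace(spec, dt=dt)
    h = sample_hrf(fine)
    half = h.max() / 2.0
    above = np.flatnonzero(h >= half)
    return (above[-1] - above[0]) * dt


def peak_time(spec: HRFSpec, dt: float = 0.01) -> float:
    """Time of the kernel maximum, seconds."""
    fine = replace(spec, dt=dt)
    return float(np.argmax(sample_hrf(fine)) * dt)


#: Width factors of the default HRF family used in mismatch experiments.
#: Moderate steps keep the kernels in the physiological range; at these
#: widths the size bias of a mismatched fit is monotone in the width, while
#: extreme dilations would shift the response peak so far that the lag
#: (which inflates the apparent size regardless of sign) dominates.
DEFAULT_WIDTH_FACTORS = (0.85, 1.0, 1.15, 1.3)


def default_hrf_set(dt: float = 1.0) -> dict[str, HRFSpec]:
    """Four all-positive HRFs with strictly increasing width.

    A width-scaled family of the Boynton kernel, standing in for the
    distinct default HRFs that different analysis tools assume. The lack of
    an undershoot makes the width -> pRF-size bias mechanism easiest to see;
    the same qualitative behavior holds for undershooting shapes.
    """
    base = HRFSpec(form="boynton", dt=dt)
    return {
        f"boynton-w{f:g}": scale_width(base, f) for f in DEFAULT_WIDTH_FACTORS
    }


#: Named presets addressable from configs and the command line.
def named_hrf(name: str, dt: float = 1.0) -> HRFSpec:
    """Resolve an HRF preset by name ('canonical', 'boynton', 'boynton-w1.35', ...)."""
    if name == "canonical":
        return HRFSpec(form="two_gamma", dt=dt)
    if name == "boynton":
        return HRFSpec(form="boynton", dt=dt)
    if name.startswith("boynton-w"):
        try:
            factor = float(name[len("boynton-w"):])
        except ValueError:
            raise ValueError(f"unknown HRF preset: {name!r}") from None
        return scale_width(HRFSpec(form="boynton", dt=dt), factor)
    raise ValueError(f"unknown HRF preset: {name!r}")
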