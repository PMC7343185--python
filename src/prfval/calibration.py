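"""Noise-level estimation from on/off block-design scans.

An on/off scan alternates full-field stimulation with rest at a fixed cycle
period, so responsive voxels carry a near-sinusoidal modulation at the
stimulus frequency. The procedure: (1) keep voxels whose mean signal is at
least 75% of the grand mean; (2) among those, keep voxels within 80% of the
maximum spectral coherence at the stimulus frequency; (3) convert to
percent signal change and keep modulation amplitudes in the 8-12% band;
(4) fit a cycle-locked sinusoid per surviving voxel — the residual is the
noise estimate, and SNR is the rms ratio of fit to residual in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .noise import measure_snr

__all__ = [
    "OnOffScan",
    "stimulus_frequency",
    "psc",
    "coherence",
    "fit_cycle_sinusoid",
    "select_voxels",
    "estimate_snr_from_scan",
    "pick_noise_quantile_voxels",
]


@dataclass(frozen=True)
class OnOffScan:
    """Raw-unit BOLD array (n_voxels x n_frames) from a block-design run."""

    bold: np.ndarray
    tr: float
    cycle_period_sec: float = 24.0
    n_cycles: int = 8

    def __post_init__(self):
        if self.n_cycles < 2:
            raise ValueError("an on/off scan needs at least 2 cycles")
        duration = self.bold.shape[1] * self.tr
        if abs(duration - self.n_cycles * self.cycle_period_sec) > self.cycle_period_sec:
            raise ValueError(
                "scan duration is inconsistent with n_cycles * cycle_period_sec"
            )


def stimulus_frequency(cycle_period_sec: float) -> float:
    """Stimulus frequency in Hz (e.g. a 24 s cycle -> 0.0417 Hz)."""
    if cycle_period_sec <= 0:
        raise ValueError("cycle period must be positive")
    return 1.0 / cycle_period_sec


def psc(series: np.ndarray) -> np.ndarray:
    """Percent signal change: subtract and divide by the temporal mean."""
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("cannot convert a zero-mean series to percent signal change")
    return (series - mean) / mean * 100.0


def coherence(
    series: np.ndarray, stim_freq_hz: float, tr: float, window_bins: int = 10
) -> float:
    """Spectral coherence at the stimulus frequency.

    Amplitude at the discrete frequency bin nearest ``stim_freq_hz`` divided
    by the mean amplitude over the +/- ``window_bins`` neighboring bins
    (stimulus bin excluded). Flat-spectrum noise gives values near 1;
    a strong cycle-locked response gives values well above 1.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 2 * window_bins:
        raise ValueError("series too short for the requested coherence window")
    amp = np.abs(np.fft.rfft(series - series.mean()))
    freqs = np.fft.rfftfreq(n, d=tr)
    k = int(np.argmin(np.abs(freqs - stim_freq_hz)))
    lo, hi = max(k - window_bins, 1), min(k + window_bins, amp.size - 1)
    neighbors = np.r_[amp[lo:k], amp[k + 1 : hi + 1]]
    if neighbors.size == 0:
        raise ValueError("stimulus bin sits at the spectrum edge: empty window")
    return float(amp[k] / neighbors.mean())


def fit_cycle_sinusoid(series: np.ndarray, n_cycles: int):
    """Least-squares fit of A*sin(2*pi*n_cycles*t/T + phi) + offset.

    Returns (amplitude, phase, fitted_series). Linear in sin/cos basis, so
    the fit is exact for inputs in the model class.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    series = np.asarray(series, dtype=float)
    n = series.size
    arg = 2.0 * np.pi * n_cycles * np.arange(n) / n
    design = np.column_stack([np.sin(arg), np.cos(arg), np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, series, rcond=None)
    a_sin, a_cos, offset = coef
    amplitude = float(np.hypot(a_sin, a_cos))
    phase = float(np.arctan2(a_cos, a_sin))
    fitted = design @ coef
    return amplitude, phase, fitted


def modulation_amplitude_psc(series: np.ndarray) -> float:
    """Peak-to-peak modulation of the PSC series divided by 2 (percent).

    A +/-10% modulation therefore reads as 10.
    """
    p = psc(series)
    return float((p.max() - p.min()) / 2.0)


def select_voxels(
    scan: OnOffScan,
    mean_fraction: float = 0.75,
    coherence_fraction: float = 0.80,
    psc_band: tuple[float, float] = (8.0, 12.0),
    window_bins: int = 10,
):
    """Three-stage voxel filter for calibration voxels.

    Stages, applied in order: mean signal >= ``mean_fraction`` of the grand
    mean; coherence >= ``coherence_fraction`` of the stage-1 maximum; PSC
    modulation amplitude inside ``psc_band``. Returns (indices, stage_counts)
    where stage_counts lists the survivor count after each stage. An empty
    survivor set at any stage short-circuits with empty indices.
    """
    bold = np.asarray(scan.bold, dtype=float)
    n_vox = bold.shape[0]
    counts = []

    means = bold.mean(axis=1)
    grand = means.mean()
    if grand <= 0:  # no signal anywhere: nothing can pass the mean filter
        return np.array([], dtype=int), [0, 0, 0]
    stage1 = np.flatnonzero(means >= mean_fraction * grand)
    counts.append(stage1.size)
    if stage1.size == 0:
        return stage1, counts + [0, 0]

    f0 = stimulus_frequency(scan.cycle_period_sec)
    cohs = np.array(
        [coherence(bold[i], f0, scan.tr, window_bins) for i in stage1]
    )
    stage2 = stage1[cohs >= coherence_fraction * cohs.max()]
    counts.append(stage2.size)
    if stage2.size == 0:
        return stage2, counts + [0]

    amps = np.array([modulation_amplitude_psc(bold[i]) for i in stage2])
    keep = (amps >= psc_band[0]) & (amps <= psc_band[1])
    stage3 = stage2[keep]
    counts.append(stage3.size)
    return stage3, counts


def estimate_snr_from_scan(scan: OnOffScan, voxel_idx: int):
    """SNR (dB) of one voxel: cycle-sinusoid fit vs its residual.

    The voxel's PSC series is fit with an ``n_cycles`` sinusoid; the noise
    is the residual, and SNR = 20*log10(rms(fit)/rms(residual)). Returns
    (snr_db, residual_series).
    """
    series = psc(scan.bold[voxel_idx])
    _, _, fitted = fit_cycle_sinusoid(series, scan.n_cycles)
    residual = series - fitted
    modulation = fitted - fitted.mean()
    rms_mod = np.sqrt(np.mean(modulation**2))
    if np.sqrt(np.mean(residual**2)) <= 1e-9 * max(rms_mod, 1e-12):
        raise ValueError("residual is numerically zero: SNR is infinite")
    return measure_snr(modulation, residual), residual


def pick_noise_quantile_voxels(
    scan: OnOffScan, survivors, quantiles=(0.95, 0.45, 0.10)
):
    """Pick representative voxels at given quantiles of residual-noise rms.

    Quantiles are taken over the survivor voxels' residual rms (ascending);
    the defaults pick a high-, mid- and low-noise representative.
    """
    survivors = np.asarray(survivors)
    if survivors.size == 0:
        return np.array([], dtype=int)
    rms = np.array(
        [np.sqrt(np.mean(estimate_snr_from_scan(scan, i)[1] ** 2)) for i in survivors]
    )
    order = np.argsort(rms)
    picks = []
    for q in quantiles:
        pos = int(round(q * (survivors.size - 1)))
        picks.append(int(survivors[order[pos]]))
    return np.array(picks, dtype=int)
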