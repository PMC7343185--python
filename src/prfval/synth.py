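"""The BOLD forward model and batch synthesis of ground-truth datasets.

Pipeline per voxel: the frame-wise inner product of the binary stimulus
aperture with the receptive-field matrix gives the neural response time
series; causal convolution with the unit-sum HRF kernel gives the noise-free
BOLD response; the response is scaled so a unit-gain pRF produces a
configured peak modulation (percent signal change around a zero baseline);
parameterized noise is added last. The identical noise-free path is what
the reference fitter inverts, so synthesis and fitting share one forward
implementation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .hrf import HRFSpec, sample_hrf
from .noise import NoiseSpec, generate_noise, noise_preset
from .prf import DoGPRF, GaussianPRF, evaluate_field
from .stimulus import Stimulus

__all__ = [
    "neural_response",
    "causal_convolve",
    "convolve_and_scale",
    "noise_free_bold",
    "response_contrast",
    "synthesize_voxel",
    "SynthesisConfig",
    "SyntheticDataset",
    "synthesize_dataset",
    "write_bids",
    "read_bids",
    "voxel_seed",
]

#: default peak modulation of the noise-free signal for a unit-gain pRF,
#: percent signal change (mid of the 8-12% band used for voxel calibration)
DEFAULT_AMPLITUDE_PSC = 10.0


def neural_response(stimulus: Stimulus, rf_field: np.ndarray) -> np.ndarray:
    """Frame-wise inner product of aperture and receptive field.

    Blank (all-zero) frames map to exactly zero response.
    """
    rf_field = np.asarray(rf_field, dtype=float)
    if rf_field.shape != stimulus.aperture.shape[:2]:
        raise ValueError(
            f"RF field shape {rf_field.shape} does not match stimulus spatial "
            f"shape {stimulus.aperture.shape[:2]}"
        )
    return rf_field.reshape(-1) @ stimulus.as_matrix()


def causal_convolve(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution, zero history before frame 0, truncated to len(series)."""
    series = np.asarray(series, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size > series.size:
        raise ValueError("HRF kernel is longer than the time series")
    return np.convolve(series, kernel)[: series.size]


def convolve_and_scale(
    series: np.ndarray,
    kernel: np.ndarray,
    amplitude_psc: float = DEFAULT_AMPLITUDE_PSC,
    baseline: float = 0.0,
) -> np.ndarray:
    """Convolve with the HRF and scale the peak modulation to ``amplitude_psc``.

    The convolved series is scaled so its largest absolute excursion equals
    ``amplitude_psc`` (percent signal change) on top of ``baseline``. An
    all-zero response stays flat at baseline.
    """
    conv = causal_convolve(series, kernel)
    peak = np.max(np.abs(conv))
    if peak == 0:
        return np.full_like(conv, baseline)
    return baseline + amplitude_psc * conv / peak


def noise_free_bold(
    prf,
    stimulus: Stimulus,
    kernel: np.ndarray,
    amplitude_psc: float = DEFAULT_AMPLITUDE_PSC,
    baseline: float = 0.0,
) -> np.ndarray:
    """Noise-free BOLD for a pRF; linear in the pRF gain.

    The peak-modulation scaling is anchored to the *unit-gain* response so
    that doubling the gain exactly doubles the modulation (a gain-1 pRF
    peaks at ``amplitude_psc``).
    """
    gain = prf.gain
    field_ = evaluate_field(prf, stimulus.grid)
    unit_field = field_ / gain if gain != 0 else field_
    resp = neural_response(stimulus, unit_field)
    modulation = convolve_and_scale(resp, kernel, amplitude_psc, baseline=0.0)
    return baseline + gain * modulation


def response_contrast(prf, stimulus: Stimulus, kernel: np.ndarray) -> float:
    """RMS modulation of the convolved (unscaled) response to a stimulus.

    A sweeping bar drives the response to sustained extremes through
    temporal summation under the HRF; randomizing the frame order destroys
    that summation, so the same frames yield a lower rms modulation (the
    SNR cost of randomized designs). Measured before percent-signal
    scaling, which would otherwise hide the difference.
    """
    field_ = evaluate_field(prf, stimulus.grid)
    conv = causal_convolve(neural_response(stimulus, field_), kernel)
    return float(np.std(conv))


def voxel_seed(master_seed: int, index: int) -> int:
    """Per-voxel seed derived from the master seed and the voxel counter."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def synthesize_voxel(
    prf,
    stimulus: Stimulus,
    hrf_spec: HRFSpec,
    noise_spec: NoiseSpec,
    seed: int | None = None,
    amplitude_psc: float = DEFAULT_AMPLITUDE_PSC,
    baseline: float = 0.0,
) -> np.ndarray:
    """One synthetic BOLD time series: noise-free forward model plus noise."""
    kernel = sample_hrf(replace(hrf_spec, dt=stimulus.frame_duration_sec))
    clean = noise_free_bold(prf, stimulus, kernel, amplitude_psc, baseline)
    if noise_spec.is_silent:
        return clean
    use_seed = seed if seed is not None else noise_spec.seed
    noise = generate_noise(
        replace(noise_spec, seed=use_seed),
        stimulus.n_frames,
        stimulus.frame_duration_sec,
    )
    return clean + noise


def _prf_truth_fields(prf) -> dict:
    if isinstance(prf, GaussianPRF):
        return {
            "prf_type": "gaussian",
            "x0": prf.x0,
            "y0": prf.y0,
            "sigma_major": prf.sigma_major,
            "sigma_minor": prf.sigma_minor,
            "theta": prf.theta,
            "gain": prf.gain,
        }
    if isinstance(prf, DoGPRF):
        c = prf.center
        return {
            "prf_type": "dog",
            "x0": c.x0,
            "y0": c.y0,
            "sigma_major": c.sigma_major,
            "sigma_minor": c.sigma_minor,
            "theta": c.theta,
            "gain": c.gain,
            "surround_sigma_major": prf.surround_sigma_major,
            "rel_amplitude": prf.rel_amplitude,
        }
    raise TypeError(f"unsupported pRF type: {type(prf).__name__}")


@dataclass(frozen=True)
class SynthesisConfig:
    """Condition grid for batch synthesis: the Cartesian product of pRFs,
    HRFs and noise levels, repeated ``repetitions`` times each."""

    prfs: Sequence
    hrfs: dict  # name -> HRFSpec
    noise_levels: Sequence[str] = ("none",)
    repetitions: int = 1
    master_seed: int = 0
    amplitude_psc: float = DEFAULT_AMPLITUDE_PSC

    def __post_init__(self):
        if not self.prfs or not self.hrfs or not self.noise_levels:
            raise ValueError("pRF, HRF and noise-level lists must be non-empty")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class SyntheticDataset:
    """Voxel-by-time BOLD array paired with its per-voxel ground-truth table."""

    bold: np.ndarray  # (n_voxels, n_frames), percent signal change
    tr: float
    truth: pd.DataFrame  # one row per voxel
    stimulus_ref: str = ""

    def __post_init__(self):
        if self.bold.shape[0] != len(self.truth):
            raise ValueError("one ground-truth row per voxel is required")

    @property
    def n_voxels(self) -> int:
        return self.bold.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bold.shape[1]


def synthesize_dataset(config: SynthesisConfig, stimulus: Stimulus) -> SyntheticDataset:
    """Synthesize the full condition grid; fully reproducible from the master seed."""
    rows = []
    series = []
    idx = 0
    for prf in config.prfs:
        for hrf_id, hrf_spec in config.hrfs.items():
            for level in config.noise_levels:
                nspec = level if isinstance(level, NoiseSpec) else noise_preset(level)
                level_name = level if isinstance(level, str) else "custom"
                for rep in range(config.repetitions):
                    seed = voxel_seed(config.master_seed, idx)
                    bold = synthesize_voxel(
                        prf,
                        stimulus,
                        hrf_spec,
                        nspec,
                        seed=seed,
                        amplitude_psc=config.amplitude_psc,
                    )
                    row = {"voxel_id": idx, **_prf_truth_fields(prf)}
                    row.update(
                        hrf_id=hrf_id,
                        hrf_form=hrf_spec.form,
                        hrf_width_scale=hrf_spec.width_scale,
                        noise_level=level_name,
                        repetition=rep,
                        seed=seed,
                        design=stimulus.design_label,
                    )
                    rows.append(row)
                    series.append(bold)
                    idx += 1
    return SyntheticDataset(
        bold=np.asarray(series),
        tr=stimulus.frame_duration_sec,
        truth=pd.DataFrame(rows),
        stimulus_ref=stimulus.design_label,
    )


# ---------------------------------------------------------------------------
# BIDS layout: voxels as a one-dimensional NIfTI (nVoxels x 1 x 1 x nFrames)
# under sub-<label>/func/, truth table under derivatives/prfsynth/.

_BOLD_PATTERN = re.compile(r"sub-(?P<sub>[^_/]+)_task-(?P<task>[^_/]+)_bold\.nii(\.gz)?$")


def write_bids(
    dataset: SyntheticDataset, root, subject: str = "001", task: str = "prf"
) -> Path:
    root = Path(root)
    func = root / f"sub-{subject}" / "func"
    func.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{subject}_task-{task}"
    data = dataset.bold[:, None, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr))
    nib.save(img, str(func / f"{stem}_bold.nii.gz"))
    (func / f"{stem}_bold.json").write_text(
        json.dumps({"RepetitionTime": dataset.tr, "TaskName": task}, indent=2)
    )
    deriv = root / "derivatives" / "prfsynth" / f"sub-{subject}"
    deriv.mkdir(parents=True, exist_ok=True)
    dataset.truth.to_csv(deriv / f"{stem}_truth.tsv", sep="\t", index=False)
    (root / "dataset_description.json").write_text(
        json.dumps({"Name": "prfval synthetic dataset", "BIDSVersion": "1.8.0"}, indent=2)
    )
    return root


def read_bids(root, subject: str | None = None, task: str = "prf") -> SyntheticDataset:
    root = Path(root)
    candidates = sorted(root.glob("sub-*/func/*_bold.nii.gz")) + sorted(
        root.glob("sub-*/func/*_bold.nii")
    )
    if subject is not None:
        candidates = [c for c in candidates if c.name.startswith(f"sub-{subject}_")]
    if not candidates:
        raise FileNotFoundError(
            "no sub-*/func/*_bold.nii[.gz] file found: missing 'sub' entity "
            f"under {root}"
        )
    bold_path = candidates[0]
    m = _BOLD_PATTERN.search(bold_path.name)
    if m is None:
        raise ValueError(f"malformed BIDS bold filename: {bold_path.name}")
    sub, task = m.group("sub"), m.group("task")
    sidecar = bold_path.with_name(bold_path.name.split("_bold")[0] + "_bold.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing bold sidecar (RepetitionTime): {sidecar}")
    tr = float(json.loads(sidecar.read_text())["RepetitionTime"])
    data = np.asarray(nib.load(str(bold_path)).get_fdata())
    if data.ndim != 4:
        raise ValueError("bold NIfTI must be 4-D (voxels x 1 x 1 x frames)")
    bold = data.reshape(data.shape[0], data.shape[3])
    truth_path = (
        root / "derivatives" / "prfsynth" / f"sub-{sub}" / f"sub-{sub}_task-{task}_truth.tsv"
    )
    if not truth_path.exists():
        raise FileNotFoundError(f"missing ground-truth derivative table: {truth_path}")
    truth = pd.read_csv(truth_path, sep="\t")
    return SyntheticDataset(bold=bold, tr=tr, truth=truth)
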