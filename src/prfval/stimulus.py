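"""Visual-field stimulus apertures for pRF mapping.

A stimulus is a movie of binary apertures (1 where stimulus contrast is
present) defined on a square visual-field grid. The default protocol is a
bar that sweeps the field along several directions with interleaved blank
periods; a randomized variant permutes the temporal order of the same
frames, which is the standard manipulation for decoupling stimulus position
from the temporal smear of the hemodynamic response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VisualFieldGrid",
    "BarSweepSpec",
    "Stimulus",
    "make_grid",
    "generate_aperture",
    "write_stimulus",
    "read_stimulus",
]


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square sampling lattice over the visual field.

    The grid has an odd number of rows and columns so that the central
    sample maps exactly onto (0, 0) degrees. Column index increases with x
    (rightward); row index increases downward, i.e. decreases with y.
    """

    field_extent_deg: float
    n_rows: int
    n_cols: int

    @property
    def deg_per_sample(self) -> float:
        return self.field_extent_deg / (self.n_rows - 1)

    @property
    def center_index(self) -> tuple[int, int]:
        return (self.n_rows // 2, self.n_cols // 2)

    def index_to_deg(self, row, col):
        """Map sample indices to (x, y) in degrees of visual angle."""
        cr, cc = self.center_index
        d = self.deg_per_sample
        x = (np.asarray(col) - cc) * d
        y = (cr - np.asarray(row)) * d
        return x, y

    def deg_to_index(self, x, y):
        """Inverse of :meth:`index_to_deg` (exact on the lattice)."""
        cr, cc = self.center_index
        d = self.deg_per_sample
        col = np.asarray(x) / d + cc
        row = cr - np.asarray(y) / d
        return row, col

    def mesh_deg(self):
        """(X, Y) coordinate arrays of shape (n_rows, n_cols), degrees."""
        cr, cc = self.center_index
        d = self.deg_per_sample
        x = (np.arange(self.n_cols) - cc) * d
        y = (cr - np.arange(self.n_rows)) * d
        return np.meshgrid(x, y)


def make_grid(field_extent_deg: float = 20.0, n_samples: int = 101) -> VisualFieldGrid:
    """Build the visual-field grid (default 20 deg across, 101 x 101 samples).

    ``n_samples`` must be odd so that the central sample sits exactly at
    (0, 0) degrees.
    """
    if field_extent_deg <= 0:
        raise ValueError("field_extent_deg must be positive")
    if n_samples < 3 or n_samples % 2 == 0:
        raise ValueError(
            "n_samples must be odd and >= 3 so the central sample maps to (0, 0) deg"
        )
    return VisualFieldGrid(field_extent_deg, n_samples, n_samples)


#: default motion directions (degrees, counterclockwise from +x): four axes,
#: both directions — L→R, R→L, D→U, U→D, and the two diagonals each way.
DEFAULT_SWEEP_DIRECTIONS = (0.0, 180.0, 90.0, 270.0, 45.0, 225.0, 135.0, 315.0)


@dataclass(frozen=True)
class BarSweepSpec:
    """Bar-sweep protocol parameters.

    With the defaults (8 sweeps of 18 s at 1 s frames, a 14 s blank after
    every second sweep) the movie is exactly 200 frames long. Slower
    protocols lengthen the total duration at fixed frame rate; blank
    periods scale proportionally.
    """

    bar_width_deg: float = 2.0
    sweep_directions_deg: Sequence[float] = field(default=DEFAULT_SWEEP_DIRECTIONS)
    seconds_per_sweep: float = 18.0
    frame_duration_sec: float = 1.0
    blank_sec: float | None = None  # per blank period; None = 14 * sps / 18
    blank_every: int = 2  # insert a blank after every this-many sweeps
    randomize: bool = False
    seed: int | None = None

    @property
    def frames_per_sweep(self) -> int:
        return int(round(self.seconds_per_sweep / self.frame_duration_sec))

    @property
    def frames_per_blank(self) -> int:
        blank = self.blank_sec
        if blank is None:
            blank = 14.0 * self.seconds_per_sweep / 18.0
        return int(round(blank / self.frame_duration_sec))

    @property
    def total_frames(self) -> int:
        n_sweeps = len(self.sweep_directions_deg)
        n_blanks = n_sweeps // self.blank_every if self.blank_every > 0 else 0
        return n_sweeps * self.frames_per_sweep + n_blanks * self.frames_per_blank


@dataclass(frozen=True)
class Stimulus:
    """Binary aperture movie plus its grid and timing metadata."""

    aperture: np.ndarray  # (rows, cols, frames), uint8, values in {0, 1}
    frame_duration_sec: float
    grid: VisualFieldGrid
    design_label: str = "sweep"
    seed: int | None = None

    def __post_init__(self):
        ap = self.aperture
        if ap.ndim != 3:
            raise ValueError("aperture must be rows x cols x frames")
        if ap.shape[0] != self.grid.n_rows or ap.shape[1] != self.grid.n_cols:
            raise ValueError("aperture spatial shape does not match grid")
        if ap.shape[2] < 1:
            raise ValueError("aperture must contain at least one frame")
        vals = np.unique(ap)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("aperture values must be exactly 0 or 1")

    @property
    def n_frames(self) -> int:
        return self.aperture.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Flattened (n_pixels, n_frames) float view for inner products."""
        r, c, t = self.aperture.shape
        return self.aperture.reshape(r * c, t).astype(float)


def _sweep_frames(spec: BarSweepSpec, grid: VisualFieldGrid) -> np.ndarray:
    """Render all sweep frames (blanks included) in presentation order."""
    if len(spec.sweep_directions_deg) == 0:
        raise ValueError("at least one sweep direction is required")
    if spec.bar_width_deg > grid.field_extent_deg:
        raise ValueError("bar is wider than the visual field")
    if spec.total_frames <= 0:
        raise ValueError("protocol produces zero frames")

    X, Y = grid.mesh_deg()
    half_extent = grid.field_extent_deg / 2.0
    m = spec.frames_per_sweep
    frames = []
    for i, direction in enumerate(spec.sweep_directions_deg):
        phi = np.deg2rad(direction)
        ux, uy = np.cos(phi), np.sin(phi)
        # snap numerically-zero components so axis-aligned opposite sweeps
        # are exact time-reverses of each other
        ux = 0.0 if abs(ux) < 1e-9 else ux
        uy = 0.0 if abs(uy) < 1e-9 else uy
        proj = X * ux + Y * uy
        # bar center travels the full field extent along the motion axis;
        # antisymmetrized so forward/backward sweeps are exact time-reverses
        centers = np.linspace(-half_extent, half_extent, m)
        centers = (centers - centers[::-1]) / 2.0
        for c in centers:
            frames.append(np.abs(proj - c) <= spec.bar_width_deg / 2.0)
        if spec.blank_every > 0 and (i + 1) % spec.blank_every == 0:
            for _ in range(spec.frames_per_blank):
                frames.append(np.zeros_like(X, dtype=bool))
    return np.stack(frames, axis=-1).astype(np.uint8)


def generate_aperture(spec: BarSweepSpec, grid: VisualFieldGrid) -> Stimulus:
    """Generate the bar-sweep (or randomized-order) aperture movie.

    In sweep mode the bar advances monotonically within each sweep. In
    randomized mode the *same frames* are emitted in a seed-determined
    permutation of temporal order, so the two designs are signal-matched
    frame-for-frame (identical frame multisets).
    """
    if spec.randomize and spec.seed is None:
        raise ValueError("randomized ordering requires a seed")
    movie = _sweep_frames(spec, grid)
    label = "sweep"
    if spec.randomize:
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(movie.shape[2])
        movie = movie[:, :, order]
        label = "random"
    return Stimulus(
        aperture=movie,
        frame_duration_sec=spec.frame_duration_sec,
        grid=grid,
        design_label=label,
        seed=spec.seed,
    )


def default_stimulus(**overrides) -> Stimulus:
    """The default 20-deg, 101x101x200 bar-sweep stimulus."""
    spec = replace(BarSweepSpec(), **overrides) if overrides else BarSweepSpec()
    return generate_aperture(spec, make_grid())


# ---------------------------------------------------------------------------
# NIfTI round trip: on disk the movie is (rows, cols, 1, frames) uint8 with a
# JSON sidecar carrying the visual-field metadata.

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stimulus(stimulus: Stimulus, path) -> Path:
    path = Path(path)
    data = stimulus.aperture[:, :, None, :].astype(np.uint8)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    sidecar = {
        "FieldExtentDeg": stimulus.grid.field_extent_deg,
        "FrameDurationSec": stimulus.frame_duration_sec,
        "DesignLabel": stimulus.design_label,
        "Seed": stimulus.seed,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stimulus(path) -> Stimulus:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"stimulus sidecar {sidecar_file} is missing (FieldExtentDeg / "
            "FrameDurationSec metadata required)"
        )
    meta = json.loads(sidecar_file.read_text())
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError("stimulus NIfTI must have shape rows x cols x 1 x frames")
    movie = data[:, :, 0, :]
    bad = np.sum((movie != 0) & (movie != 1))
    if bad:
        raise ValueError(f"stimulus file is not binary: {int(bad)} offending entries")
    grid = make_grid(meta["FieldExtentDeg"], movie.shape[0])
    return Stimulus(
        aperture=movie.astype(np.uint8),
        frame_duration_sec=float(meta["FrameDurationSec"]),
        grid=grid,
        design_label=meta.get("DesignLabel", "sweep"),
        seed=meta.get("Seed"),
    )
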